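"""sgRNA target-site extraction, oligo-pool design, and input encoding.

Coordinates are 0-based half-open and always reported on the plus strand of
the contig.  Sequences attached to a :class:`TargetSite` (protospacer, PAM,
flanks) are stored in guide orientation, i.e. already reverse-complemented
for minus-strand sites, so that ``upstream + protospacer + pam + downstream``
is the contiguous 43-nt guide-strand window for every site.

Protospacer positions are numbered 1 (PAM-proximal) to 20 (PAM-distal)
throughout.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import iupac_regex, revcomp, validate_acgt

PROTOSPACER_LEN = 20
PAM_LEN = 3
FLANK_LEN = 10
WINDOW_LEN = PROTOSPACER_LEN + PAM_LEN + 2 * FLANK_LEN  # 43

# BsaI Golden-Gate cloning flanks appended when emitting oligo pools.
CLONING_FLANK5 = "CCTGGTTCTTGGTCTCTCACG"
CLONING_FLANK3 = "GTTTTAGAGACCGCTGCCAGTTCATTTCTTAGGG"

#: default transversion per base (purine <-> pyrimidine)
DEFAULT_TRANSVERSION_MAP = {"A": "C", "C": "A", "G": "T", "T": "G"}

ONEHOT_ROWS = "ACGT"


@dataclass
class GenomeSequence:
    """A named DNA sequence, optionally circular (plasmid)."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        self.sequence = self.sequence.upper()
        if any(c not in "ACGTN" for c in self.sequence):
            raise ValueError("sequence may contain only A/C/G/T/N")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Plus-strand subsequence [start, end); wraps if circular."""
        n = len(self.sequence)
        if self.circular:
            start %= n
            end = start + (end - start)
            if end <= n:
                return self.sequence[start:end]
            reps = self.sequence * (2 + (end - start) // n)
            return reps[start:end]
        if start < 0 or end > n:
            raise IndexError(f"[{start}, {end}) outside linear sequence of length {n}")
        return self.sequence[start:end]


@dataclass
class TargetSite:
    """A PAM-anchored target locus in guide orientation."""

    contig: str
    strand: str
    protospacer: str
    pam: str
    upstream: str
    downstream: str
    protospacer_start: int
    tev_site: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM must be NGG, got {self.pam!r}")

    @property
    def window43(self) -> str:
        return self.upstream + self.protospacer + self.pam + self.downstream

    def pam_proximal_kmer(self, k: int) -> str:
        """The k protospacer nucleotides adjacent to the PAM."""
        return self.protospacer[PROTOSPACER_LEN - k:]


@dataclass
class PoolEntry:
    name: str
    guide20: str
    category: str  # exact | mismatch | non_targeting
    parent: str | None = None
    mutated_positions: list[int] = field(default_factory=list)


@dataclass
class GuidePool:
    entries: list[PoolEntry]
    flank5: str = CLONING_FLANK5
    flank3: str = CLONING_FLANK3

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            dup = [n for n, c in Counter(names).items() if c > 1]
            raise ValueError(f"duplicate pool entry names: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    def category_counts(self) -> dict[str, int]:
        return dict(Counter(e.category for e in self.entries))

    def oligo(self, entry: PoolEntry) -> str:
        return self.flank5 + entry.guide20 + self.flank3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "guide20": [e.guide20 for e in self.entries],
                "category": [e.category for e in self.entries],
                "parent": [e.parent or "" for e in self.entries],
                "mutated_positions": [
                    ",".join(map(str, e.mutated_positions)) for e in self.entries
                ],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, flank5: str = CLONING_FLANK5,
                 flank3: str = CLONING_FLANK3) -> "GuidePool":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        entries = [
            PoolEntry(
                name=r["name"],
                guide20=r["guide20"],
                category=r.get("category", "exact") or "exact",
                parent=r.get("parent") or None,
                mutated_positions=[int(x) for x in r.get("mutated_positions", "").split(",") if x],
            )
            for _, r in df.iterrows()
        ]
        return cls(entries, flank5=flank5, flank3=flank3)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.name}\n{self.oligo(e)}\n")


@dataclass
class EncodedInput:
    """A one-hot encoded model input: 4 x N binary matrix, rows A,C,G,T."""

    sequence: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (4, len(self.sequence)):
            raise ValueError("matrix must be 4 x len(sequence)")


# ---------------------------------------------------------------------------
# PAM scanning
# ---------------------------------------------------------------------------

def _scan_one_strand(seq: str, n: int, circular: bool, pam_re) -> Iterable[int]:
    """Yield protospacer start offsets (in ``seq`` coordinates, which may be
    the doubled sequence for circular genomes)."""
    limit = len(seq) - (PROTOSPACER_LEN + PAM_LEN + FLANK_LEN)
    for p in range(FLANK_LEN, limit + 1):
        if circular and p - FLANK_LEN >= n:
            break
        if pam_re.match(seq, p + PROTOSPACER_LEN):
            yield p


def scan_pam_sites(
    genome: GenomeSequence,
    pam_pattern: str = "NGG",
    tev_range: tuple[int, int] | None = None,
) -> list[TargetSite]:
    """Find every PAM-adjacent 20-nt protospacer whose full 43-nt window fits.

    Both strands are scanned.  Windows wrap around the origin for circular
    sequences; linear sequences drop edge sites.  Windows containing N are
    skipped.  When ``tev_range=(min_offset, max_offset)`` is given, each
    site's ``tev_site`` flag is set by :func:`detect_tev_motif` using
    upstream context pulled from the genome.

    Returns sites sorted by (contig, protospacer_start, strand).
    """
    if len(pam_pattern) != PAM_LEN:
        raise ValueError("pam_pattern must be 3 nt")
    pam_re = iupac_regex(pam_pattern)
    n = len(genome)
    if n < WINDOW_LEN and not genome.circular:
        warnings.warn(
            f"sequence {genome.id!r} shorter than the {WINDOW_LEN}-nt window; no sites",
            stacklevel=2,
        )
        return []

    sites: list[TargetSite] = []
    fwd = genome.sequence + (genome.sequence[: WINDOW_LEN - 1] if genome.circular else "")
    rev = revcomp(genome.sequence)
    rev = rev + (rev[: WINDOW_LEN - 1] if genome.circular else "")

    def build(seq: str, p: int, strand: str) -> TargetSite | None:
        window = seq[p - FLANK_LEN: p + PROTOSPACER_LEN + PAM_LEN + FLANK_LEN]
        if "N" in window:
            return None
        if strand == "+":
            start = (p % n) if genome.circular else p
        else:
            # p is in revcomp coordinates; protospacer occupies rc[p:p+20]
            start = n - (p % n) - PROTOSPACER_LEN if genome.circular else n - p - PROTOSPACER_LEN
            start %= n
        return TargetSite(
            contig=genome.id,
            strand=strand,
            protospacer=window[FLANK_LEN: FLANK_LEN + PROTOSPACER_LEN],
            pam=window[FLANK_LEN + PROTOSPACER_LEN: FLANK_LEN + PROTOSPACER_LEN + PAM_LEN],
            upstream=window[:FLANK_LEN],
            downstream=window[FLANK_LEN + PROTOSPACER_LEN + PAM_LEN:],
            protospacer_start=start,
        )

    for strand, seq in (("+", fwd), ("-", rev)):
        for p in _scan_one_strand(seq, n, genome.circular, pam_re):
            site = build(seq, p, strand)
            if site is not None:
                sites.append(site)

    if tev_range is not None:
        min_off, max_off = tev_range
        need = max_off + 4
        for i, site in enumerate(sites):
            ctx = _upstream_context(genome, site, need)
            if ctx is not None and len(ctx) >= need:
                sites[i] = replace(site, tev_site=_tev_in_context(ctx, min_off, max_off))

    sites.sort(key=lambda s: (s.contig, s.protospacer_start, s.strand))
    return sites


def _upstream_context(genome: GenomeSequence, site: TargetSite, length: int) -> str | None:
    """Guide-strand sequence immediately 5' of the protospacer, or None if a
    linear sequence does not hold enough context."""
    n = len(genome)
    if site.strand == "+":
        start, end = site.protospacer_start - length, site.protospacer_start
        if not genome.circular and start < 0:
            return None
        return genome.fetch(start, end)
    # minus strand: upstream of the guide is downstream on the plus strand
    start = site.protospacer_start + PROTOSPACER_LEN
    end = start + length
    if not genome.circular and end > n:
        return None
    return revcomp(genome.fetch(start, end))


def _tev_in_context(upstream: str, min_offset: int, max_offset: int) -> bool:
    """C-N-N-N-G with the G ``d`` nt upstream of the protospacer 5' end for
    some d in [min_offset, max_offset]; d=1 means immediately adjacent."""
    m = len(upstream)
    for d in range(min_offset, max_offset + 1):
        g = m - d  # index of the motif G, d nt upstream (d=1: adjacent)
        c = g - 4
        if c >= 0 and upstream[g] == "G" and upstream[c] == "C":
            return True
    return False


def detect_tev_motif(site: TargetSite, spacer_range: tuple[int, int] = (13, 17)) -> bool:
    """True iff a 5'-CNNNG-3' motif lies upstream of the protospacer with its
    G at an offset within ``spacer_range`` of the protospacer 5' end.

    Uses the site's stored upstream context; raises ``ValueError`` when that
    context is too short for ``spacer_range`` (caller must supply a longer
    window, e.g. via :func:`scan_pam_sites` with ``tev_range``).
    """
    min_off, max_off = spacer_range
    if min_off < 1 or max_off < min_off:
        raise ValueError("spacer_range must satisfy 1 <= min <= max")
    if len(site.upstream) < max_off + 4:
        raise ValueError(
            f"need >= {max_off + 4} nt of upstream context, site stores {len(site.upstream)}"
        )
    return _tev_in_context(site.upstream, min_off, max_off)


# ---------------------------------------------------------------------------
# Pools
# ---------------------------------------------------------------------------

def tile_transversions(
    guide20: str,
    transversion_map: dict[str, str] | None = None,
) -> list[tuple[str, list[int]]]:
    """All single- and adjacent-double-transversion variants of a guide.

    Returns exactly 39 variants in deterministic order: 20 single-position
    variants for positions 1..20 (PAM-proximal to PAM-distal), then 19
    adjacent-dinucleotide variants for position pairs (1,2)..(19,20).
    """
    validate_acgt(guide20, "guide")
    if len(guide20) != PROTOSPACER_LEN:
        raise ValueError("guide must be 20 nt")
    tmap = dict(DEFAULT_TRANSVERSION_MAP if transversion_map is None else transversion_map)
    for base, sub in tmap.items():
        purines, pyrimidines = "AG", "CT"
        if (base in purines) == (sub in purines):
            raise ValueError(f"{base}->{sub} is not a transversion")

    def mutate(positions: list[int]) -> str:
        chars = list(guide20)
        for pos in positions:  # position 1 = PAM-proximal = last string index
            idx = PROTOSPACER_LEN - pos
            chars[idx] = tmap[chars[idx]]
        return "".join(chars)

    variants = [(mutate([p]), [p]) for p in range(1, PROTOSPACER_LEN + 1)]
    variants += [(mutate([p, p + 1]), [p, p + 1]) for p in range(1, PROTOSPACER_LEN)]
    return variants


def build_mpool(
    parents: Sequence[tuple[str, str]],
    non_targeting: Sequence[tuple[str, str]],
    transversion_map: dict[str, str] | None = None,
    flank5: str = CLONING_FLANK5,
    flank3: str = CLONING_FLANK3,
) -> GuidePool:
    """Mismatch oligo pool: per parent one exact guide plus all 39 tiled
    transversion variants, then the non-targeting controls."""
    entries: list[PoolEntry] = []
    for name, guide in parents:
        entries.append(PoolEntry(name=name, guide20=guide, category="exact"))
        for variant, positions in tile_transversions(guide, transversion_map):
            tag = "_".join(map(str, positions))
            entries.append(
                PoolEntry(
                    name=f"{name}_m{tag}",
                    guide20=variant,
                    category="mismatch",
                    parent=name,
                    mutated_positions=list(positions),
                )
            )
    for name, guide in non_targeting:
        entries.append(PoolEntry(name=name, guide20=guide, category="non_targeting"))
    return GuidePool(entries, flank5=flank5, flank3=flank3)


# ---------------------------------------------------------------------------
# Off-target exclusion
# ---------------------------------------------------------------------------

def _pam_adjacent_kmers(genome: GenomeSequence, k: int, pam_pattern: str) -> Counter:
    """Multiset of k-mers immediately 5' of an NGG PAM, both strands."""
    pam_re = iupac_regex(pam_pattern)
    n = len(genome)
    kmers: Counter = Counter()
    for seq in (genome.sequence, revcomp(genome.sequence)):
        ext = seq + (seq[: k + PAM_LEN - 1] if genome.circular else "")
        for p in range(k, len(ext) - PAM_LEN + 1):
            if genome.circular and p - k >= n:
                break
            if pam_re.match(ext, p):
                kmer = ext[p - k: p]
                if "N" not in kmer:
                    kmers[kmer] += 1
    return kmers


def filter_offtargets(
    sites: list[TargetSite],
    genome: GenomeSequence,
    k: int = 15,
    pam_pattern: str = "NGG",
) -> list[TargetSite]:
    """Drop sites whose PAM-proximal k-mer occurs PAM-adjacent anywhere else.

    A site's own locus contributes one occurrence; any additional
    PAM-adjacent occurrence of its k-mer (either strand) excludes it.
    Idempotent and monotone: retained sites are returned unchanged.
    """
    if not 1 <= k <= PROTOSPACER_LEN:
        raise ValueError("k must be in 1..20")
    occurrences = _pam_adjacent_kmers(genome, k, pam_pattern)
    return [s for s in sites if occurrences[s.pam_proximal_kmer(k)] <= 1]


# ---------------------------------------------------------------------------
# Windows and encoding
# ---------------------------------------------------------------------------

def build_input_window(site: TargetSite, upstream_nt: int, downstream_nt: int) -> str:
    """Contiguous guide-strand window of length 20+upstream_nt+downstream_nt.

    ``downstream_nt`` counts the PAM first: downstream_nt=3 is
    protospacer+PAM; the default model input is (0, 8) -> 28 nt.
    """
    if not 0 <= upstream_nt <= len(site.upstream):
        raise ValueError(f"upstream_nt must be in 0..{len(site.upstream)}")
    tail = site.pam + site.downstream
    if not 0 <= downstream_nt <= len(tail):
        raise ValueError(f"downstream_nt must be in 0..{len(tail)}")
    up = site.upstream[len(site.upstream) - upstream_nt:] if upstream_nt else ""
    return up + site.protospacer + tail[:downstream_nt]


def window_from_context(context43: str, upstream_nt: int, downstream_nt: int) -> str:
    """Same as :func:`build_input_window` but from a bare 43-nt window string."""
    if len(context43) != WINDOW_LEN:
        raise ValueError("context must be 43 nt")
    if not 0 <= upstream_nt <= FLANK_LEN or not 0 <= downstream_nt <= PAM_LEN + FLANK_LEN:
        raise ValueError("window request out of range")
    start = FLANK_LEN - upstream_nt
    end = FLANK_LEN + PROTOSPACER_LEN + downstream_nt
    return context43[start:end]


def encode_onehot(seq: str) -> EncodedInput:
    """One-hot encode a DNA string as a 4 x N binary matrix (rows A,C,G,T)."""
    validate_acgt(seq)
    mat = np.zeros((4, len(seq)), dtype=np.int8)
    for j, base in enumerate(seq):
        mat[ONEHOT_ROWS.index(base), j] = 1
    return EncodedInput(sequence=seq, matrix=mat)


def decode_onehot(encoded: EncodedInput | np.ndarray) -> str:
    mat = encoded.matrix if isinstance(encoded, EncodedInput) else encoded
    if mat.ndim != 2 or mat.shape[0] != 4 or not np.all(mat.sum(axis=0) == 1):
        raise ValueError("not a valid 4 x N one-hot matrix")
    return "".join(ONEHOT_ROWS[i] for i in np.argmax(mat, axis=0))


def encode_batch(seqs: Sequence[str]) -> np.ndarray:
    """Stack one-hot encodings into a float array of shape (n, 4, N)."""
    if not seqs:
        raise ValueError("no sequences")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("sequences must have uniform length")
    return np.stack([encode_onehot(s).matrix for s in seqs]).astype(np.float64)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def sites_to_frame(sites: Sequence[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [s.contig for s in sites],
            "start": [s.protospacer_start for s in sites],
            "end": [s.protospacer_start + PROTOSPACER_LEN for s in sites],
            "strand": [s.strand for s in sites],
            "protospacer": [s.protospacer for s in sites],
            "pam": [s.pam for s in sites],
            "upstream10": [s.upstream for s in sites],
            "downstream10": [s.downstream for s in sites],
            "tev_site": [s.tev_site for s in sites],
        }
    )


def sites_to_bed(sites: Sequence[TargetSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.protospacer_start}\t{s.protospacer_start + PROTOSPACER_LEN}"
                f"\t{s.protospacer}\t0\t{s.strand}\n"
            )


def frame_to_sites(df: pd.DataFrame) -> list[TargetSite]:
    return [
        TargetSite(
            contig=r["contig"],
            strand=r["strand"],
            protospacer=r["protospacer"],
            pam=r["pam"],
            upstream=r["upstream10"],
            downstream=r["downstream10"],
            protospacer_start=int(r["start"]),
            tev_site=bool(r.get("tev_site", False)),
        )
        for _, r in df.iterrows()
    ]
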