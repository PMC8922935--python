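"""CCCH zinc-finger motif detection and protein architecture typing.

The CCCH motif is a small zinc-coordinating module of three cysteines and a
histidine with variable inter-residue spacers, written

    C-X{a}-C-X{b}-C-X3-H

where ``a`` (spacer1) and ``b`` (spacer2) are the numbers of arbitrary
residues between C1/C2 and C2/C3, and exactly three residues separate C3 from
the histidine.  Plant genomes additionally carry tandem zinc fingers (TZF):
a long-spacer finger (a in {7,8}, b = 5), a linker of 16 or 18 residues, and
a short-spacer finger (a = 5, b = 4).  A TZF preceded by an arginine-rich
region is an RR-TZF; an RR-TZF protein that also carries an ankyrin-repeat
domain is an ANK-RR-TZF.

Scanning is greedy and left-to-right: at each cysteine the match with the
smallest spacer1 (then smallest spacer2) wins, and the scanner resumes after
the matched histidine.  This makes tandem-finger counting deterministic.
Ambiguity codes (X, B, Z, J, U, O) never match C or H but are legal spacer
residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZJUO"
ALLOWED_AA = set(STANDARD_AA) | set(AMBIGUOUS_AA)

#: spacer1/spacer2 ranges of the broad consensus
DEFAULT_SPACER1 = (4, 17)
DEFAULT_SPACER2 = (4, 6)
#: narrower spacer1 preset used by some census conventions
NARROW_SPACER1 = (5, 17)

#: residues between C3 and the histidine (fixed by the motif definition)
SPACER3 = 3

#: TZF geometry: finger1 spacers, admissible linker lengths, finger2 spacers
TZF_FINGER1_SPACER1 = (7, 8)
TZF_FINGER1_SPACER2 = 5
TZF_LINKERS = (16, 18)
TZF_FINGER2_SPACER1 = 5
TZF_FINGER2_SPACER2 = 4

#: arginine-rich region defaults: window upstream of finger1, minimum R count
RR_WINDOW = 30
RR_MIN_ARG = 6

ARCHITECTURES = ("CCCH", "TZF", "RR-TZF", "ANK-RR-TZF")


@dataclass(frozen=True)
class MotifHit:
    """A located CCCH motif; coordinates are 0-based half-open residues."""

    protein_id: str
    start: int
    end: int
    spacer1: int
    spacer2: int

    @property
    def type_label(self) -> str:
        return f"C-X{self.spacer1}-C-X{self.spacer2}-C-X3-H"

    def __post_init__(self) -> None:
        if self.end - self.start != self.spacer1 + self.spacer2 + SPACER3 + 4:
            raise ValueError(
                f"inconsistent hit span for {self.protein_id}: "
                f"[{self.start},{self.end}) vs spacers "
                f"({self.spacer1},{self.spacer2})"
            )


@dataclass(frozen=True)
class TzfSpan:
    """Two CCCH fingers forming a tandem zinc finger."""

    finger1: MotifHit
    finger2: MotifHit

    @property
    def linker_length(self) -> int:
        return self.finger2.start - self.finger1.end

    @property
    def start(self) -> int:
        return self.finger1.start

    @property
    def end(self) -> int:
        return self.finger2.end


@dataclass
class ArchitectureCall:
    """Per-protein architecture label with the evidence behind it."""

    protein_id: str
    motif_count: int
    motif_types: Counter
    architecture: str
    extra_domains: frozenset = field(default_factory=frozenset)


@dataclass
class MotifCensus:
    """Proteome-wide motif tally.

    ``per_type`` is sorted by count descending, ties broken by label.
    """

    per_type: list  # list of (type_label, count)
    total_motifs: int
    total_proteins: int

    @property
    def mean_motifs_per_protein(self) -> float:
        return self.total_motifs / self.total_proteins

    @classmethod
    def from_counts(cls, per_type_counts: dict, n_proteins: int) -> "MotifCensus":
        if n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        ordered = sorted(per_type_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(ordered, sum(per_type_counts.values()), n_proteins)


def _validate_sequence(sequence: str) -> None:
    for pos, ch in enumerate(sequence):
        if ch not in ALLOWED_AA:
            raise ValueError(
                f"illegal residue {ch!r} at position {pos} "
                "(expected one of the 20 amino acids or X/B/Z/J/U/O)"
            )


def _match_at(sequence, start, spacer1_range, spacer2_range):
    """Smallest-(spacer1, spacer2) match anchored at ``start``, or None."""
    n = len(sequence)
    if sequence[start] != "C":
        return None
    for a in range(spacer1_range[0], spacer1_range[1] + 1):
        c2 = start + 1 + a
        if c2 >= n or sequence[c2] != "C":
            continue
        for b in range(spacer2_range[0], spacer2_range[1] + 1):
            c3 = c2 + 1 + b
            h = c3 + 1 + SPACER3
            if h < n and sequence[c3] == "C" and sequence[h] == "H":
                return a, b
    return None


def scan_ccch(
    sequence: str,
    protein_id: str = "",
    spacer1_range: tuple = DEFAULT_SPACER1,
    spacer2_range: tuple = DEFAULT_SPACER2,
) -> list:
    """Greedy left-to-right non-overlapping CCCH scan.

    Returns hits sorted by start.  An empty sequence yields an empty list;
    residues outside the amino-acid alphabet raise ``ValueError`` naming the
    offending position.
    """
    _validate_sequence(sequence)
    hits = []
    i = 0
    n = len(sequence)
    while i < n:
        m = _match_at(sequence, i, spacer1_range, spacer2_range)
        if m is None:
            i += 1
            continue
        a, b = m
        end = i + a + b + SPACER3 + 4
        hits.append(MotifHit(protein_id, i, end, a, b))
        i = end  # consume through the matched H
    return hits


def detect_tzf(hits: list, sequence: str) -> list:
    """Pair scanned fingers into tandem zinc fingers.

    Fingers must be a (7|8, 5) motif and a (5, 4) motif separated by a 16- or
    18-residue linker.  Pairing is greedy left-to-right and no finger is used
    twice.
    """
    spans = []
    used = set()
    ordered = sorted(hits, key=lambda h: h.start)
    for i, h1 in enumerate(ordered):
        if i in used:
            continue
        if h1.spacer1 not in TZF_FINGER1_SPACER1 or h1.spacer2 != TZF_FINGER1_SPACER2:
            continue
        for j in range(i + 1, len(ordered)):
            if j in used:
                continue
            h2 = ordered[j]
            if (
                h2.spacer1 == TZF_FINGER2_SPACER1
                and h2.spacer2 == TZF_FINGER2_SPACER2
                and h2.start - h1.end in TZF_LINKERS
            ):
                spans.append(TzfSpan(h1, h2))
                used.update((i, j))
                break
    return spans


def detect_rr(
    sequence: str,
    tzf: TzfSpan,
    window_length: int = RR_WINDOW,
    min_arginines: int = RR_MIN_ARG,
) -> bool:
    """True iff the window upstream of finger1 is arginine-rich.

    The window covers ``window_length`` residues immediately before the first
    finger, truncated at the N-terminus.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    lo = max(0, tzf.finger1.start - window_length)
    window = sequence[lo : tzf.finger1.start]
    return window.count("R") >= min_arginines


def classify_architecture(
    protein_id: str,
    hits: list,
    tzf_spans: list,
    rr_flags: list,
    external_domains=(),
) -> ArchitectureCall:
    """Assign the architecture label of one protein.

    ``rr_flags`` carries one boolean per TZF span (``detect_rr`` output).
    ``external_domains`` are domain names (KH/RRM/RING/ANK) taken from an
    external annotation table, never predicted here.
    """
    if not hits:
        raise ValueError(f"{protein_id}: not a CCCH protein (zero motifs)")
    if len(rr_flags) != len(tzf_spans):
        raise ValueError("rr_flags must align with tzf_spans")
    domains = frozenset(external_domains)
    has_tzf = bool(tzf_spans)
    has_rr = any(rr_flags)
    if has_tzf and has_rr and "ANK" in domains:
        arch = "ANK-RR-TZF"
    elif has_tzf and has_rr:
        arch = "RR-TZF"
    elif has_tzf:
        arch = "TZF"
    else:
        arch = "CCCH"
    return ArchitectureCall(
        protein_id=protein_id,
        motif_count=len(hits),
        motif_types=Counter(h.type_label for h in hits),
        architecture=arch,
        extra_domains=domains,
    )


def motif_census(hits: list, n_proteins: int) -> MotifCensus:
    """Tally motif types over a whole proteome's hits."""
    counts = Counter(h.type_label for h in hits)
    return MotifCensus.from_counts(dict(counts), n_proteins)


def scan_protein(
    protein_id: str,
    sequence: str,
    spacer1_range: tuple = DEFAULT_SPACER1,
    spacer2_range: tuple = DEFAULT_SPACER2,
    rr_window: int = RR_WINDOW,
    rr_min_arg: int = RR_MIN_ARG,
    external_domains=(),
):
    """Full per-protein workflow: scan, pair TZFs, test RR, classify.

    Returns ``(hits, tzf_spans, call_or_None)``; the call is None when the
    protein carries no motif (it is not a family member).
    """
    hits = scan_ccch(sequence, protein_id, spacer1_range, spacer2_range)
    if not hits:
        return hits, [], None
    spans = detect_tzf(hits, sequence)
    flags = [detect_rr(sequence, s, rr_window, rr_min_arg) for s in spans]
    call = classify_architecture(protein_id, hits, spans, flags, external_domains)
    return hits, spans, call
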