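"""Host/symbiont partitioning of holobiont meta-transcriptome assemblies.

Coral RNA-seq libraries contain a mixture of transcripts from the coral
animal and its dinoflagellate endosymbionts (plus minor players).  This
module separates the two pools using, in order of precedence:

1. ortholog evidence against a coral reference genome/transcriptome,
2. ortholog evidence against a symbiont reference,
3. reciprocal best BLAST hits (RBH) to a cnidarian sequence database,
4. a GC-content rule for the remainder: coral transcripts sit on the
   AT-rich side of a pronounced bimodal GC distribution, so unclassified
   transcripts with GC <= cutoff (default 0.47) are assigned to the host.

Prefilters (summed-FPKM expression floor, open-reading-frame requirement)
are applied before homology classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

COMPLEMENT = str.maketrans("ACGTacgtNnRYSWKMBDHVryswkmbdhv",
                           "TGCAtgcaNnYRSWMKVHDByrswmkvhdb")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: databases a homology-evidence row may refer to
DATABASES = ("coral_reference", "symbiont_reference", "cnidarian_db")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Orf:
    """Open reading frame in 0-based half-open forward-strand coordinates."""

    start: int
    end: int
    frame: int
    strand: str  # '+' or '-'

    def __iter__(self):
        return iter((self.start, self.end, self.frame, self.strand))

    @property
    def n_codons(self) -> int:
        """Coding codons, excluding the stop codon."""
        return (self.end - self.start) // 3 - 1


@dataclass
class Transcript:
    id: str
    sequence: str
    gc_fraction: float = None  # type: ignore[assignment]
    orfs: list = field(default_factory=list)

    def __post_init__(self):
        if self.gc_fraction is None:
            self.gc_fraction = compute_gc(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


class UndefinedGcError(ValueError):
    """Raised when a sequence contains no unambiguous A/C/G/T base."""


def compute_gc(sequence: str) -> float:
    """GC fraction over unambiguous bases only.

    Ambiguity codes (N etc.) are excluded from both numerator and
    denominator.  Raises :class:`UndefinedGcError` if no A/C/G/T base
    is present.
    """
    if not sequence:
        raise UndefinedGcError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedGcError("sequence contains only ambiguous bases")
    return gc / (gc + at)


def _orfs_forward(seq: str, min_codons: int):
    """All ATG->stop ORFs on the given strand, reading the string as-is."""
    n = len(seq)
    out = []
    for frame in range(3):
        # positions of stops per frame, scanned once
        i = frame
        starts: list[int] = []
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if codon == "ATG":
                starts.append(i)
            if codon in STOP_CODONS:
                for s in starts:
                    if (i + 3 - s) // 3 - 1 >= min_codons:
                        out.append((s, i + 3, frame))
                starts = []
            i += 3
    return out


def find_orfs(sequence: str, min_codons: int = 100) -> list[Orf]:
    """Find every ORF (ATG...stop, standard code) on both strands.

    Each ATG with an in-frame downstream stop codon yields one ORF,
    so nested ORFs sharing a stop are all reported.  Coordinates are
    0-based half-open on the *forward* strand regardless of the strand
    the ORF lies on; ``frame`` is the frame on the ORF's own strand.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    orfs = [Orf(s, e, f, "+") for s, e, f in _orfs_forward(seq, min_codons)]
    rc = reverse_complement(seq)
    for s, e, f in _orfs_forward(rc, min_codons):
        orfs.append(Orf(n - e, n - s, f, "-"))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def filter_low_expression(fpkm: pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Transcripts whose FPKM summed across samples is >= threshold.

    Rows summing strictly below the threshold are removed (a sum exactly
    equal to the threshold is retained).
    """
    if fpkm.empty:
        raise ValueError("empty FPKM matrix")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sums = fpkm.sum(axis=1)
    return list(fpkm.index[sums >= threshold])


def _best_hits(hits: pd.DataFrame, by: str, other: str) -> dict:
    """Best-scoring partner per `by` id; ties broken lexicographically."""
    best: dict = {}
    for row in hits.itertuples(index=False):
        q = getattr(row, by)
        s = getattr(row, other)
        sc = row.score
        if q not in best or sc > best[q][0] or (sc == best[q][0] and s < best[q][1]):
            best[q] = (sc, s)
    return {q: s for q, (sc, s) in best.items()}


def reciprocal_best_hits(forward: pd.DataFrame, reverse: pd.DataFrame) -> set:
    """Query ids whose best subject's own best query is that query.

    Both tables need columns ``query_id``, ``subject_id``, ``score``.
    Ties on score are broken toward the lexicographically smaller
    partner id before reciprocity is checked.
    """
    fwd_best = _best_hits(forward, "query_id", "subject_id")
    rev_best = _best_hits(reverse, "query_id", "subject_id")
    return {q for q, s in fwd_best.items() if rev_best.get(s) == q}


EVIDENCE_KINDS = (
    "ortholog_coral", "ortholog_symbiont", "rbh_cnidarian",
    "gc_rule", "gc_fail", "no_orf", "low_expression", "ortholog_conflict",
)


def classify_transcripts(
    transcripts,
    evidence: pd.DataFrame | None = None,
    gc_cutoff: float = 0.47,
    low_expression_ids=(),
    no_orf_ids=(),
    rbh_ids=(),
) -> pd.DataFrame:
    """Assign each transcript to host, symbiont, or discarded.

    Precedence: prefilters (low expression, then missing ORF) discard
    first; then coral-reference ortholog evidence -> host; symbiont
    ortholog -> symbiont; evidence against both references is treated as
    conflicting and discarded; RBH to the cnidarian database -> host;
    finally the GC rule: gc <= gc_cutoff -> host, else discarded.

    ``evidence`` needs columns ``query_id``, ``database`` (one of
    ``coral_reference``/``symbiont_reference``/``cnidarian_db``) and,
    for cnidarian rows, ``reciprocal``.  ``rbh_ids`` may supply
    additional precomputed RBH query ids.

    Returns a DataFrame with one row per transcript:
    transcript_id, label in {host, symbiont, discarded}, evidence kind.
    """
    ids = {t.id for t in transcripts}
    coral: set = set()
    symb: set = set()
    rbh = set(rbh_ids)
    if evidence is not None and len(evidence):
        unknown = set(evidence["query_id"]) - ids
        if unknown:
            raise KeyError(f"evidence refers to unknown transcripts: {sorted(unknown)[:5]}")
        for row in evidence.itertuples(index=False):
            if row.database == "coral_reference":
                coral.add(row.query_id)
            elif row.database == "symbiont_reference":
                symb.add(row.query_id)
            elif row.database == "cnidarian_db":
                if getattr(row, "reciprocal", False):
                    rbh.add(row.query_id)
            else:
                raise ValueError(f"unknown database {row.database!r}")
    low = set(low_expression_ids)
    noorf = set(no_orf_ids)

    rows = []
    for t in transcripts:
        if t.id in low:
            call = ("discarded", "low_expression")
        elif t.id in noorf:
            call = ("discarded", "no_orf")
        elif t.id in coral and t.id in symb:
            call = ("discarded", "ortholog_conflict")
        elif t.id in coral:
            call = ("host", "ortholog_coral")
        elif t.id in symb:
            call = ("symbiont", "ortholog_symbiont")
        elif t.id in rbh:
            call = ("host", "rbh_cnidarian")
        elif t.gc_fraction <= gc_cutoff:
            call = ("host", "gc_rule")
        else:
            call = ("discarded", "gc_fail")
        rows.append((t.id, *call))
    return pd.DataFrame(rows, columns=["transcript_id", "label", "evidence"])


def partition_accuracy(calls: pd.DataFrame, true_origin: dict) -> float:
    """Fraction of host/symbiont decisions matching the true origin.

    The GC rule only ever admits transcripts into the host set, so a
    transcript discarded for failing the GC cutoff (evidence
    ``gc_fail``) counts as a symbiont decision; transcripts discarded
    by prefilters or conflicting evidence are excluded from the
    denominator.
    """
    pred = calls["label"].where(calls["evidence"] != "gc_fail", "symbiont")
    decided = pred.isin(["host", "symbiont"])
    truth = calls["transcript_id"].map(true_origin)
    return float((pred[decided] == truth[decided]).mean())
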