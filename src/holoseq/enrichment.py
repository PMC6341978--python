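"""GO-term overrepresentation via Pfam -> GO annotation transfer.

GO terms are attached to genes through their Pfam domain hits using the
flat pfam2go mapping (no GO-graph ancestor propagation — term sizes are
those of the flat transfer).  Overrepresentation of a term in a gene
set of interest is scored with the hypergeometric upper tail

    p = P(X >= count),  X ~ Hypergeom(|universe|, size, |test set|),

and reporting keeps terms with p below alpha that cover at least a
minimum fraction (default 2%) of the test set.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

from scipy import stats

PFAM2GO_RE = re.compile(
    r"^Pfam:(?P<pfam>PF\d+)\s+(?P<name>\S+)\s*>\s*GO:(?P<goname>.*?)\s*;\s*(?P<go>GO:\d+)\s*$")


def parse_pfam2go(text: str) -> dict:
    """pfam2go flat text -> {pfam accession: set of GO ids}.

    Comment lines start with '!'; malformed lines produce a warning and
    are skipped.
    """
    mapping: dict[str, set] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        m = PFAM2GO_RE.match(line)
        if not m:
            warnings.warn(f"skipping malformed pfam2go line {lineno}: {line!r}")
            continue
        mapping.setdefault(m["pfam"], set()).add(m["go"])
    return mapping


def genes_per_term(domain_table, pfam_to_go: dict) -> dict:
    """Per-GO-term gene sets from a gene->domain table.

    ``domain_table`` is a DataFrame with columns gene_id, domain.
    """
    term_genes: dict[str, set] = {}
    for row in domain_table.itertuples(index=False):
        for go in pfam_to_go.get(row.domain, ()):
            term_genes.setdefault(go, set()).add(row.gene_id)
    return term_genes


@dataclass
class GoTermStat:
    term_id: str
    count: int
    size: int
    expected: float
    odds_ratio: float
    p: float


def hypergeom_enrich(test_set, term_annotations: dict, universe) -> list[GoTermStat]:
    """Hypergeometric overrepresentation of each term in a test set.

    ``term_annotations`` maps term -> gene set; genes outside the
    universe are ignored, and the test set must be a subset of the
    universe.  The odds ratio uses the 2x2 table
    (count, test-count, size-count, rest), with infinity when the
    complementary cell is empty.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    test = set(test_set) & universe
    if set(test_set) - universe:
        raise ValueError("test set must be contained in the universe")
    n_u, n_t = len(universe), len(test)
    out = []
    for term, genes in sorted(term_annotations.items()):
        members = set(genes) & universe
        size = len(members)
        if size == 0:
            continue
        count = len(test & members)
        p = float(stats.hypergeom.sf(count - 1, n_u, size, n_t))
        expected = size * n_t / n_u
        a, b = count, n_t - count
        c, d = size - count, n_u - size - n_t + count
        odds = math.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else math.nan)
        out.append(GoTermStat(term, count, size, expected, odds, p))
    out.sort(key=lambda s: (s.p, s.term_id))
    return out


def filter_terms(term_stats, test_set_size: int, alpha: float = 0.05,
                 min_fraction: float = 0.02) -> list[GoTermStat]:
    """Reporting filter: p < alpha and count >= ceil(min_fraction * n)."""
    min_count = math.ceil(min_fraction * test_set_size)
    return [s for s in term_stats if s.p < alpha and s.count >= min_count]
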