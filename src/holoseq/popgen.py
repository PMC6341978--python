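"""Transcriptome-SNP population genetics.

From VCF genotypes called against a host transcriptome reference:
quality filtering (per-genotype depth, site call rate, minor allele
frequency), synonymous annotation against open reading frames,
one-SNP-per-transcript thinning, the multi-locus Weir & Cockerham
(1984) F_ST estimator theta with percentile bootstrap confidence
intervals over loci, and 2x2 chi-square tests of independence.

The WC84 estimator decomposes allele-frequency variance into components
a (among populations), b (among individuals within populations) and c
(within individuals); the multi-locus estimate is the ratio of sums
theta = sum(a) / sum(a + b + c).  Negative estimates are retained, as
usual for this estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .simulate import balding_nichols_genotypes


@dataclass
class SnpRecord:
    transcript_id: str
    position: int  # 1-based on the transcript
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray  # per-sample alt dosage 0/1/2, NaN = missing
    depths: np.ndarray  # per-sample read depth
    synonymous: bool | None = None

    @property
    def maf(self) -> float:
        g = self.genotypes[~np.isnan(self.genotypes)]
        if g.size == 0:
            return np.nan
        p = g.sum() / (2 * g.size)
        return float(min(p, 1 - p))


def read_vcf(path):
    """Read a VCF 4.x with GT and DP fields -> (records, sample names).

    Multi-allelic sites are kept here (dropped by :func:`filter_snps`);
    their genotypes are reduced to first-ALT dosage.
    """
    import pysam

    records: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            gts = np.full(len(samples), np.nan)
            dps = np.zeros(len(samples))
            for i, s in enumerate(samples):
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is not None and None not in gt:
                    gts[i] = sum(1 for al in gt if al == 1)
                dp = call.get("DP")
                dps[i] = 0 if dp is None else dp
            alts = rec.alts or ("N",)
            records.append(SnpRecord(rec.chrom, rec.pos, rec.ref, alts[0],
                                     gts, dps))
            if len(alts) > 1:
                records[-1].alt_allele = ",".join(alts)
    return records, samples


def filter_snps(records, maf_min: float = 0.1, call_rate_min: float = 0.95,
                depth_min: int = 20) -> list:
    """Depth, call-rate and MAF filtering of biallelic SNPs.

    Genotype calls with depth below ``depth_min`` are set missing; a
    site is kept when it is biallelic, its remaining call rate is at
    least ``call_rate_min`` and its minor allele frequency (among the
    remaining calls) is at least ``maf_min``.
    """
    out = []
    for r in records:
        if "," in r.alt_allele or len(r.ref_allele) != 1 or len(r.alt_allele) != 1:
            continue
        g = r.genotypes.copy()
        g[r.depths < depth_min] = np.nan
        called = ~np.isnan(g)
        if called.mean() < call_rate_min:
            continue
        p = g[called].sum() / (2 * called.sum())
        if min(p, 1 - p) < maf_min:
            continue
        out.append(SnpRecord(r.transcript_id, r.position, r.ref_allele,
                             r.alt_allele, g, r.depths, r.synonymous))
    return out


def annotate_synonymous(record: SnpRecord, orf, sequence: str) -> bool | None:
    """Whether ref and alt codons translate identically (standard code).

    ``orf`` provides ``start``/``end`` (0-based half-open, forward
    strand) and ``strand``.  SNPs outside the ORF return None
    (undetermined, excluded from the synonymous set).
    """
    pos0 = record.position - 1
    if pos0 < 0 or pos0 >= len(sequence):
        raise IndexError(f"position {record.position} outside transcript "
                         f"{record.transcript_id}")
    start, end, strand = orf.start, orf.end, orf.strand
    if not start <= pos0 < end:
        return None
    seq = sequence.upper()
    if strand == "+":
        off = pos0 - start
        cstart = start + 3 * (off // 3)
        codon = seq[cstart:cstart + 3]
        within = off % 3
        ref_b, alt_b = record.ref_allele.upper(), record.alt_allele.upper()
    else:
        # read codons off the reverse strand
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        off = (end - 1) - pos0
        within = off % 3
        cstart_rev = 3 * (off // 3)
        rc = str(Seq(seq[start:end]).reverse_complement())
        codon = rc[cstart_rev:cstart_rev + 3]
        ref_b, alt_b = comp[record.ref_allele.upper()], comp[record.alt_allele.upper()]
    if len(codon) < 3:
        return None
    if codon[within] != ref_b:
        raise ValueError(f"reference allele mismatch at {record.transcript_id}:"
                         f"{record.position} (codon {codon}, within {within})")
    alt_codon = codon[:within] + alt_b + codon[within + 1:]
    return str(Seq(codon).translate()) == str(Seq(alt_codon).translate())


def thin_one_per_transcript(records, isoform_table: pd.DataFrame) -> list:
    """One SNP per gene: first position on the longest isoform.

    ``isoform_table`` needs columns gene_id, isoform_id, length.  Per
    gene, only SNPs on its longest isoform (ties broken toward the
    lexicographically smallest isoform id) are considered, and the one
    with the smallest position is kept.  Genes whose isoforms carry no
    SNP contribute nothing; a SNP on an isoform absent from the table
    raises.
    """
    iso = isoform_table.sort_values(["gene_id", "length", "isoform_id"],
                                    ascending=[True, False, True])
    chosen = iso.groupby("gene_id", sort=True).first()["isoform_id"]
    iso_to_gene = dict(zip(isoform_table["isoform_id"], isoform_table["gene_id"]))
    keep_iso = set(chosen)
    best: dict[str, SnpRecord] = {}
    for r in records:
        if r.transcript_id not in iso_to_gene:
            raise KeyError(f"no isoform length for transcript {r.transcript_id}")
        if r.transcript_id not in keep_iso:
            continue
        g = iso_to_gene[r.transcript_id]
        if g not in best or r.position < best[g].position:
            best[g] = r
    return [best[g] for g in sorted(best)]


# --- Weir & Cockerham ------------------------------------------------------

@dataclass
class FstEstimate:
    theta: float
    ci_low: float | None
    ci_high: float | None
    n_loci: int
    n_bootstrap: int
    component_sums: tuple  # (sum a, sum b, sum c)


def wc_components(g1: np.ndarray, g2: np.ndarray):
    """Per-locus WC84 variance components for two populations.

    ``g1``/``g2`` are (loci x individuals) diploid alt dosages with NaN
    for missing calls.  Loci with fewer than two callable individuals
    in either group get NaN components (skipped by the callers).
    Returns (a, b, c) arrays.
    """
    r = 2
    res = []
    n1 = (~np.isnan(g1)).sum(axis=1).astype(float)
    n2 = (~np.isnan(g2)).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(g1, axis=1) / (2 * n1)
        p2 = np.nansum(g2, axis=1) / (2 * n2)
        h1 = np.nansum(g1 == 1, axis=1) / n1
        h2 = np.nansum(g2 == 1, axis=1) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                         / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _group_matrices(records, samples, groups):
    """Split records into two (loci x individuals) dosage matrices."""
    grp = pd.Series(groups)
    levels = sorted(grp.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    idx1 = [i for i, s in enumerate(samples) if grp[s] == levels[0]]
    idx2 = [i for i, s in enumerate(samples) if grp[s] == levels[1]]
    g = np.vstack([r.genotypes for r in records])
    return g[:, idx1], g[:, idx2]


def wc_fst(records, samples=None, groups=None, *, matrices=None) -> FstEstimate:
    """Multi-locus WC84 theta = sum(a) / sum(a+b+c).

    Either pass ``records`` + ``samples`` + ``groups`` (sample -> group
    mapping with exactly two levels) or two prebuilt dosage matrices via
    ``matrices=(g1, g2)``.  Monomorphic loci (zero denominator) and loci
    with fewer than two callable individuals per group are skipped.
    """
    if matrices is not None:
        g1, g2 = matrices
    else:
        g1, g2 = _group_matrices(records, samples, groups)
    a, b, c = wc_components(np.asarray(g1, float), np.asarray(g2, float))
    den = a + b + c
    ok = np.isfinite(den) & (den != 0)
    if not ok.any():
        raise ValueError("no usable loci for FST")
    theta = float(a[ok].sum() / den[ok].sum())
    return FstEstimate(theta, None, None, int(ok.sum()), 0,
                       (float(a[ok].sum()), float(b[ok].sum()), float(c[ok].sum())))


def bootstrap_ci(records=None, samples=None, groups=None, *, matrices=None,
                 n_reps: int = 1000, level: float = 0.95,
                 seed: int | None = None, rng=None):
    """Percentile bootstrap CI for theta, resampling loci with replacement."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if matrices is not None:
        g1, g2 = matrices
    else:
        g1, g2 = _group_matrices(records, samples, groups)
    a, b, c = wc_components(np.asarray(g1, float), np.asarray(g2, float))
    den = a + b + c
    ok = np.isfinite(den) & (den != 0)
    a, den = a[ok], den[ok]
    if a.size < 2:
        raise ValueError("need at least two usable loci to bootstrap")
    rng = rng if rng is not None else np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_reps, a.size))
    thetas = a[idx].sum(axis=1) / den[idx].sum(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(thetas, [alpha, 1 - alpha])
    return float(lo), float(hi)


def estimate_fst(records, samples, groups, n_reps: int = 1000,
                 level: float = 0.95, seed: int | None = None) -> FstEstimate:
    """Point estimate plus bootstrap CI in one call."""
    est = wc_fst(records, samples, groups)
    lo, hi = bootstrap_ci(records, samples, groups, n_reps=n_reps,
                          level=level, seed=seed)
    est.ci_low, est.ci_high, est.n_bootstrap = lo, hi, n_reps
    return est


# --- island model ----------------------------------------------------------

def expected_island_fst(deme_size: float, migration_rate: float,
                        n_demes: int = 2) -> float:
    """Equilibrium F_ST of a symmetric island model of diploid demes.

    F_ST ~ 1 / (1 + 4*N*m*(d/(d-1))^2); for two demes, 1/(1 + 16 N m).
    """
    a = (n_demes / (n_demes - 1)) ** 2
    return 1.0 / (1.0 + 4.0 * deme_size * migration_rate * a)


def simulate_island_fst(deme_size: float, migration_rate: float,
                        n_per_group, n_snps: int, rng,
                        maf_min: float = 0.1) -> float:
    """WC84 theta from one simulated two-deme island-model SNP panel.

    Uses the Balding-Nichols equilibrium beta approximation with
    F = expected_island_fst(N, m): per locus, group allele frequencies
    are Beta-distributed around an ancestral frequency with parameter F,
    diploid genotypes binomial, and loci drawn until ``n_snps`` pass the
    pooled MAF filter.
    """
    f = expected_island_fst(deme_size, migration_rate)
    g1, g2, _ = balding_nichols_genotypes(rng, f, n_per_group, n_snps,
                                          maf_min=maf_min)
    return wc_fst(None, matrices=(g1, g2)).theta


# --- association -----------------------------------------------------------

@dataclass
class ContingencyTest:
    table: np.ndarray
    statistic: float
    df: int
    p: float
    correction: bool


def chi2_association(table, yates: bool = False) -> ContingencyTest:
    """Pearson chi-square test of independence on a 2x2 table.

    X^2 = sum (O - E)^2 / E with expectations from the margins; with
    ``yates`` the absolute deviations are reduced by 0.5 (floored at
    zero) before squaring.  p is from the chi-square with 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin")
    exp = np.outer(rows, cols) / n
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    x2 = float((dev ** 2 / exp).sum())
    return ContingencyTest(obs, x2, 1, float(stats.chi2.sf(x2, 1)), yates)
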