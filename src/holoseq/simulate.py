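"""Synthetic holobiont data with known ground truth.

Every input the pipeline consumes can be generated here at desk scale:
a mixed host/symbiont transcript pool with distinct GC distributions,
ITS2 read pairs mixed at known clade proportions, negative-binomial
count matrices with planted differentially expressed genes and
block-correlated coexpression modules, Balding-Nichols diploid
genotypes with a known differentiation parameter, and a pfam2go-style
annotation set with one planted enriched term.

Design notes
------------
* GC content per transcript is drawn from a truncated normal around the
  pool mean (host 0.40, symbiont 0.55, sd 0.04), which places the usual
  0.47 partition cutoff near the optimal decision boundary so that
  misclassification behaviour is actually exercised.
* Genotypes follow the Balding-Nichols model: group allele frequencies
  are Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral p ~ U(0.1, 0.9),
  giving a closed-form population with E[F_ST] = F.
* Read errors are uniform substitutions only; at 75 bp, indels add
  nothing the downstream statistics are sensitive to.
* Identical configs (same seed) produce byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partition import Orf, Transcript, reverse_complement

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic holobiont, with study-scale defaults."""

    seed: int
    # meta-transcriptome
    n_host: int = 2000
    n_symbiont: int = 2000
    gc_host_mean: float = 0.40
    gc_symbiont_mean: float = 0.55
    gc_sd: float = 0.04
    min_len: int = 400
    max_len: int = 2000
    evidence_fraction: float = 0.5
    # reads
    read_length: int = 75
    error_rate: float = 0.003
    # ITS2 typing
    n_samples: int = 24
    clade_mixtures: tuple = ()  # per-sample clade-D proportion; empty -> 0/1 alternating
    n_its2_reads: int = 10000
    # expression
    n_genes: int = 2000
    n_deg_site: int = 100
    n_deg_clade: int = 100
    lfc_effect: float = 2.0
    nb_dispersion: float = 0.1
    module_spec: tuple = ((100, 0.8), (100, 0.8), (100, 0.8), (100, 0.8), (100, 0.8))
    module_traits: tuple = ()  # optional per-module trait name ('site'/'clade'/'ga') or None
    mean_library_size: float = 1.0e6
    # genotypes
    n_snps: int = 2500
    diff_param: float = 0.05
    n_per_group: tuple = (11, 6)
    mean_depth: float = 40.0
    frac_synonymous: float = 0.85
    # annotations
    n_go_terms: int = 20
    enrichment_factor: float = 1.0

    def validate(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("gc_host_mean", "gc_symbiont_mean"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.gc_sd < 0:
            raise ValueError("gc_sd must be >= 0")
        for name in ("n_host", "n_symbiont", "n_samples", "n_its2_reads",
                     "n_genes", "n_snps", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for m in self.clade_mixtures:
            if not 0 <= m <= 1:
                raise ValueError("clade mixtures must lie in [0, 1]")
        if not 0 < self.diff_param < 1:
            raise ValueError("diff_param must lie in (0, 1)")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs >= 2 diploids")
        return self


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed by entity id."""

    transcript_origin: dict = field(default_factory=dict)  # id -> 'host'|'symbiont'
    deg_labels: dict = field(default_factory=dict)  # gene -> null/site_up/...
    module_labels: dict = field(default_factory=dict)  # gene -> module id (0 = none)
    true_mixtures: dict = field(default_factory=dict)  # sample -> clade-D proportion
    true_diff_param: float | None = None
    read_origin: dict = field(default_factory=dict)  # read id -> 'C'|'D'
    snp_synonymous: dict = field(default_factory=dict)  # snp transcript -> bool
    enriched_term: str | None = None


def _rngs(config: SimulationConfig, label: str) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    tag = zlib.crc32(label.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([config.seed, tag])
    return np.random.default_rng(ss)


def _seq_exact_gc(rng: np.random.Generator, length: int, n_gc: int) -> np.ndarray:
    """Random base array with exactly n_gc G/C bases."""
    is_gc = np.zeros(length, bool)
    is_gc[rng.choice(length, size=n_gc, replace=False)] = True
    out = np.empty(length, dtype="<U1")
    out[is_gc] = rng.choice(["G", "C"], size=n_gc)
    out[~is_gc] = rng.choice(["A", "T"], size=length - n_gc)
    return out


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    return "".join(_random_codons(rng, 1, gc)[0])


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """(n, 3) array of stop-free codons with per-base GC probability gc."""
    def draw(m):
        is_gc = rng.random((m, 3)) < gc
        out = np.where(is_gc, rng.choice(["G", "C"], size=(m, 3)),
                       rng.choice(["A", "T"], size=(m, 3)))
        return out

    arr = draw(n)
    while True:
        is_stop = (arr[:, 0] == "T") & (
            ((arr[:, 1] == "A") & ((arr[:, 2] == "A") | (arr[:, 2] == "G")))
            | ((arr[:, 1] == "G") & (arr[:, 2] == "A")))
        if not is_stop.any():
            return arr
        arr[is_stop] = draw(int(is_stop.sum()))


def _repair_gc(rng: np.random.Generator, codons: np.ndarray,
               target: int) -> np.ndarray:
    """Flip single bases until the codon block has exactly target G+C.

    Flips that would create a stop codon are skipped; the walk always
    terminates because non-stop alternatives exist at every count.
    """
    flat = codons.ravel()
    n = flat.size
    for _ in range(20 * n):
        is_gc = np.isin(flat, ("G", "C"))
        delta = target - int(is_gc.sum())
        if delta == 0:
            break
        pool = np.flatnonzero(~is_gc if delta > 0 else is_gc)
        i = int(rng.choice(pool))
        new = str(rng.choice(["G", "C"] if delta > 0 else ["A", "T"]))
        c0 = 3 * (i // 3)
        codon = "".join(flat[c0:c0 + 3])
        cand = codon[:i % 3] + new + codon[i % 3 + 1:]
        if cand in STOPS:
            continue
        flat[i] = new
    return flat.reshape(codons.shape)


def _make_transcript(rng: np.random.Generator, tid: str, gc: float,
                     length: int) -> Transcript:
    """Random transcript with exact GC count and one engineered ORF >= 100 codons."""
    max_codons = (length - 6) // 3
    n_codons = int(rng.integers(100, min(max_codons, 300) + 1))
    orf_len = 3 * (n_codons + 2)  # ATG + coding + stop
    flank_len = length - orf_len
    total_gc = int(round(gc * length))
    stop = "TGA" if gc >= 0.5 else "TAA"
    stop_gc = 1 if stop == "TGA" else 0
    flank_gc = int(np.clip(round(gc * flank_len), 0, flank_len))
    mid_target = int(np.clip(total_gc - flank_gc - 1 - stop_gc, 0, 3 * n_codons))
    mid = _repair_gc(rng, _random_codons(rng, n_codons, gc), mid_target)
    orf = "ATG" + "".join(mid.ravel()) + stop
    flank = _seq_exact_gc(rng, flank_len, flank_gc) if flank_len else np.array([], dtype="<U1")
    start = int(rng.integers(0, flank_len + 1))
    seq = "".join(flank[:start]) + orf + "".join(flank[start:])
    return Transcript(tid, seq, orfs=[Orf(start, start + orf_len, start % 3, "+")])


def gen_meta_transcriptome(config: SimulationConfig):
    """Mixed host + symbiont transcript pool with homology evidence.

    Returns (transcripts, evidence table, GroundTruth).  A fraction
    ``evidence_fraction`` of transcripts receive an ortholog hit to the
    correct reference database; the rest rely on the GC rule downstream.
    """
    config.validate()
    rng = _rngs(config, "meta_transcriptome")
    transcripts: list[Transcript] = []
    truth = GroundTruth()
    ev_rows = []
    pools = (("host", config.n_host, config.gc_host_mean, "coral_reference", "Adig"),
             ("symbiont", config.n_symbiont, config.gc_symbiont_mean,
              "symbiont_reference", "Smin"))
    for origin, n, gc_mean, db, ref_prefix in pools:
        for i in range(n):
            gc = gc_mean if config.gc_sd == 0 else float(
                np.clip(rng.normal(gc_mean, config.gc_sd), 0.0, 1.0))
            length = int(rng.integers(config.min_len, config.max_len + 1))
            tid = f"{origin[:4]}_{i:05d}"
            transcripts.append(_make_transcript(rng, tid, gc, length))
            truth.transcript_origin[tid] = origin
            if rng.random() < config.evidence_fraction:
                ev_rows.append((tid, db, f"{ref_prefix}_{i:05d}",
                                float(rng.uniform(80, 500)), 1e-50, False))
    evidence = pd.DataFrame(
        ev_rows, columns=["query_id", "database", "subject_id",
                          "score", "e_value", "reciprocal"])
    return transcripts, evidence, truth


def gen_its2_references(config: SimulationConfig, length: int = 400,
                        divergence: float = 0.15):
    """A clade-C / clade-D ITS2 reference pair at the given divergence."""
    rng = _rngs(config, "its2_refs")
    ref_c = "".join(rng.choice(BASES, size=length))
    pos = rng.choice(length, size=int(round(divergence * length)), replace=False)
    d = np.array(list(ref_c))
    for p in pos:
        choices = [b for b in "ACGT" if b != d[p]]
        d[p] = choices[int(rng.integers(3))]
    return ref_c, "".join(d)


def _mutate(rng, frag: np.ndarray, error_rate: float) -> np.ndarray:
    if error_rate <= 0:
        return frag
    hit = rng.random(frag.size) < error_rate
    if hit.any():
        frag = frag.copy()
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != frag[i]]
            frag[i] = choices[int(rng.integers(3))]
    return frag


def gen_its2_reads(config: SimulationConfig, ref_c: str, ref_d: str):
    """Paired ITS2 reads per sample at the configured clade-D proportions.

    Returns (reads, truth) where reads maps sample_id -> list of
    (read_id, mate1, mate2) and truth records per-sample true mixtures
    and per-read origins.  Mate 2 is the reverse complement of the
    fragment end, as for standard FR paired-end chemistry.
    """
    config.validate()
    L = config.read_length
    for name, ref in (("refC", ref_c), ("refD", ref_d)):
        if len(ref) < 2 * L:
            raise ValueError(f"{name} shorter than one fragment (2 x read_length)")
    mixtures = config.clade_mixtures or tuple(
        (i % 2) for i in range(config.n_samples))
    if len(mixtures) != config.n_samples:
        raise ValueError("clade_mixtures length must equal n_samples")
    rng = _rngs(config, "its2_reads")
    refs = {"C": np.array(list(ref_c)), "D": np.array(list(ref_d))}
    truth = GroundTruth()
    reads: dict[str, list] = {}
    for s, mix in enumerate(mixtures):
        sample = f"S{s:02d}"
        truth.true_mixtures[sample] = float(mix)
        out = []
        origins = np.where(rng.random(config.n_its2_reads) < mix, "D", "C")
        for r, origin in enumerate(origins):
            ref = refs[origin]
            flen = int(rng.integers(2 * L, min(2 * L + 100, ref.size) + 1))
            start = int(rng.integers(0, ref.size - flen + 1))
            frag = ref[start:start + flen]
            m1 = _mutate(rng, frag[:L], config.error_rate)
            m2 = _mutate(rng, frag[-L:], config.error_rate)
            rid = f"{sample}_r{r:06d}"
            out.append((rid, "".join(m1), reverse_complement("".join(m2))))
            truth.read_origin[rid] = origin
        reads[sample] = out
    return reads, truth


def default_design(config: SimulationConfig) -> pd.DataFrame:
    """Balanced two-site / two-clade / GA-status design for n_samples."""
    n = config.n_samples
    rows = []
    for i in range(n):
        rows.append((f"S{i:02d}",
                     "waiopae" if i < n // 2 else "kiholo",
                     "C" if i % 2 == 0 else "D",
                     "healthy" if i % 4 < 2 else "ga_affected"))
    return pd.DataFrame(rows, columns=["sample_id", "site", "clade", "ga_status"]
                        ).set_index("sample_id")


def gen_counts(config: SimulationConfig, design: pd.DataFrame):
    """Negative-binomial count and FPKM matrices with planted structure.

    ``design`` must carry one row per sample with ``site``, ``clade`` and
    ``ga_status`` columns.  The first ``n_deg_site`` genes react to site,
    the next ``n_deg_clade`` to clade (alternating up/down at half the
    log2 fold change each side); the following genes form the coexpression
    modules of ``module_spec``, each sharing a latent standard-normal
    factor scaled by its loading.  Counts are gamma-Poisson with the
    configured dispersion; FPKM is computed from counts, transcript
    lengths and realized library sizes.
    """
    config.validate()
    required = {"site", "clade", "ga_status"}
    if not required <= set(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    rng = _rngs(config, "counts")
    G, S = config.n_genes, len(design)
    n_struct = config.n_deg_site + config.n_deg_clade + sum(
        size for size, _ in config.module_spec)
    if n_struct > G:
        raise ValueError("n_genes too small for planted DEGs + modules")

    truth = GroundTruth()
    genes = [f"gene_{g:05d}" for g in range(G)]
    lengths = rng.integers(500, 3001, size=G)
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    rel /= rel.sum()
    lib = rng.uniform(0.8, 1.2, size=S) * config.mean_library_size

    site = (design["site"].to_numpy() == design["site"].iloc[0]).astype(float) - 0.5
    clade = (design["clade"].to_numpy() == "D").astype(float) - 0.5
    ga = (design["ga_status"].to_numpy() != "healthy").astype(float) - 0.5
    coding = {"site": site, "clade": clade, "ga": ga}

    logfc = np.zeros((G, S))
    for g in range(G):
        truth.deg_labels[genes[g]] = "null"
        truth.module_labels[genes[g]] = 0
    idx = 0
    for kind, n_deg, vec in (("site", config.n_deg_site, site),
                             ("clade", config.n_deg_clade, clade)):
        for j in range(n_deg):
            sign = 1.0 if j % 2 == 0 else -1.0
            logfc[idx] += sign * config.lfc_effect * vec
            truth.deg_labels[genes[idx]] = f"{kind}_{'up' if sign > 0 else 'down'}"
            idx += 1
    traits = tuple(config.module_traits) + (None,) * (
        len(config.module_spec) - len(config.module_traits))
    for m, ((size, loading), trait) in enumerate(zip(config.module_spec, traits),
                                                 start=1):
        if trait is None:
            factor = rng.normal(size=S)
        else:
            t = coding[trait]
            t = (t - t.mean()) / t.std()
            factor = 0.9 * t + np.sqrt(1 - 0.9 ** 2) * rng.normal(size=S)
        for _ in range(size):
            logfc[idx] += loading * factor
            truth.module_labels[genes[idx]] = m
            idx += 1

    mu = rel[:, None] * lib[None, :] * np.exp2(logfc)
    shape = 1.0 / config.nb_dispersion
    counts = rng.poisson(rng.gamma(shape, mu / shape))
    counts_df = pd.DataFrame(counts, index=genes, columns=design.index)
    realized_lib = counts_df.sum(axis=0).to_numpy().astype(float)
    fpkm = counts / lengths[:, None] / realized_lib[None, :] * 1e9
    fpkm_df = pd.DataFrame(fpkm, index=genes, columns=design.index)
    truth.gene_lengths = dict(zip(genes, (int(x) for x in lengths)))  # type: ignore[attr-defined]
    return counts_df, fpkm_df, truth


# --- genotypes -------------------------------------------------------------

SYN_CODON = "GCT"  # Ala, four-fold degenerate at the third position


def balding_nichols_genotypes(rng: np.random.Generator, fst: float,
                              n_per_group, n_snps: int,
                              maf_min: float = 0.0):
    """Diploid dosage matrices for two groups under the Balding-Nichols model.

    Ancestral frequencies are uniform on (0.1, 0.9); group frequencies
    are Beta-distributed around them with parameter F = fst.  If
    ``maf_min`` > 0, loci are drawn until ``n_snps`` pass the pooled
    minor-allele-frequency filter.
    """
    if not 0 < fst < 1:
        raise ValueError("fst must lie in (0, 1)")
    n1, n2 = n_per_group
    g1_parts, g2_parts, freqs = [], [], []
    got = 0
    while got < n_snps:
        m = max(n_snps - got, 16)
        p = rng.uniform(0.1, 0.9, size=2 * m)
        a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
        q1 = rng.beta(a, b)
        q2 = rng.beta(a, b)
        g1 = rng.binomial(2, q1[:, None], size=(2 * m, n1))
        g2 = rng.binomial(2, q2[:, None], size=(2 * m, n2))
        af = (g1.sum(1) + g2.sum(1)) / (2 * (n1 + n2))
        keep = np.minimum(af, 1 - af) >= maf_min
        take = min(int(keep.sum()), n_snps - got)
        sel = np.flatnonzero(keep)[:take]
        g1_parts.append(g1[sel])
        g2_parts.append(g2[sel])
        freqs.append(np.column_stack([q1[sel], q2[sel]]))
        got += take
    return np.vstack(g1_parts), np.vstack(g2_parts), np.vstack(freqs)


def gen_genotypes(config: SimulationConfig):
    """Balding-Nichols diploid genotypes at controlled codon positions.

    Returns (vcf text, snp transcripts, orf table, truth).  Each SNP sits
    on its own transcript consisting of one full-length ORF; synonymous
    SNPs occupy the third position of a four-fold degenerate codon
    (GCT -> GCC), nonsynonymous ones its second position (GCT -> GAT).
    Genotypes are emitted as VCF 4.2 with GT and DP fields; per-genotype
    depth is Poisson(mean_depth).
    """
    config.validate()
    rng = _rngs(config, "genotypes")
    n1, n2 = config.n_per_group
    g1, g2, _ = balding_nichols_genotypes(
        rng, config.diff_param, (n1, n2), config.n_snps)
    genos = np.hstack([g1, g2])
    samples = [f"g1_s{i:02d}" for i in range(n1)] + [f"g2_s{i:02d}" for i in range(n2)]
    depth = rng.poisson(config.mean_depth, size=genos.shape)

    truth = GroundTruth(true_diff_param=config.diff_param)
    transcripts: list[Transcript] = []
    orf_rows = []
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)]
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    for i in range(config.n_snps):
        tid = f"snpT_{i:05d}"
        n_codons = 60
        codons = ["".join(c) for c in _random_codons(rng, n_codons, 0.45)]
        j = int(rng.integers(1, n_codons))  # codon index within the ORF body
        codons[j - 1] = SYN_CODON
        syn = bool(rng.random() < config.frac_synonymous)
        seq = "ATG" + "".join(codons) + "TAA"
        # codon j-1 of the body occupies sequence slice [3j, 3j+3)
        if syn:
            pos0, ref, alt = 3 * j + 2, "T", "C"  # GCT -> GCC (Ala/Ala)
        else:
            pos0, ref, alt = 3 * j + 1, "C", "A"  # GCT -> GAT (Ala/Asp)
        assert seq[pos0] == ref
        transcripts.append(Transcript(tid, seq,
                                      orfs=[Orf(0, len(seq), 0, "+")]))
        orf_rows.append((tid, 0, len(seq), "+", 0))
        truth.snp_synonymous[tid] = syn
        fields = [tid, str(pos0 + 1), f"snp{i:05d}", ref, alt, ".", "PASS", ".", "GT:DP"]
        fields += [f"{gt_str[int(genos[i, s])]}:{int(depth[i, s])}"
                   for s in range(len(samples))]
        lines.append("\t".join(fields))
    orf_table = pd.DataFrame(orf_rows,
                             columns=["transcript_id", "start", "end", "strand", "frame"])
    return "\n".join(lines) + "\n", transcripts, orf_table, truth


def gen_annotations(config: SimulationConfig, genes, deg_genes=()):
    """pfam2go-style mapping plus per-gene domain assignments.

    One term (the first) is planted: its genes are sampled with weight
    ``enrichment_factor`` on the supplied DEG genes and 1 elsewhere, so a
    factor of 1 means no enrichment.  Returns (pfam2go text, gene->domain
    DataFrame, truth).
    """
    config.validate()
    if config.n_go_terms < 1:
        raise ValueError("need at least one GO term")
    rng = _rngs(config, "annotations")
    genes = list(genes)
    deg = set(deg_genes)
    truth = GroundTruth()
    lines = ["!version date: synthetic", "!Mapping of Pfam entries to GO"]
    rows = []
    for t in range(config.n_go_terms):
        pf = f"PF{t + 1:05d}"
        go = f"GO:{t + 1:07d}"
        name = f"synthetic_domain_{t + 1}"
        lines.append(f"Pfam:{pf} {name} > GO:synthetic process {t + 1} ; {go}")
        size = int(rng.integers(20, max(21, len(genes) // 10)))
        if t == 0 and config.enrichment_factor != 1.0 and deg:
            w = np.array([config.enrichment_factor if g in deg else 1.0 for g in genes])
            members = rng.choice(genes, size=size, replace=False, p=w / w.sum())
            truth.enriched_term = go
        else:
            members = rng.choice(genes, size=size, replace=False)
        rows += [(g, pf) for g in members]
    table = pd.DataFrame(rows, columns=["gene_id", "domain"])
    return "\n".join(lines) + "\n", table, truth
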