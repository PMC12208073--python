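"""Synthetic multiplexed scDAb-seq experiments with known ground truth.

The generator emulates the processed matrices of a multiplexed run: each
parent sample (patient) has a binary SNP profile with a few private mutated
SNPs plus shared background variants, per-cell genotypes suffer dropout
(missing entries), and each hash antibody's CLR expression is bimodal — a
proper-signal mode for cells from that hash's sample and a background mode
for everyone else.  Sampling follows the two-stage design: ``(1-p)*C``
singlets drawn with replacement across samples and ``p*C`` multiplets built
from pairs of cells from *different* samples, whose genotypes merge by the
variant truth table and whose proper-hash signals have their mean shrunk by
20% and variance inflated by one-third.  Per-sample raw hash moments are
first drawn with sample-to-sample variation and then affinely adjusted
(``a*H + b``) so proper distributions share identical target moments across
hashes; for three or more multiplexed samples, Gaussian noise
``N(0, 0.5*sigma_H^2)`` is added to the improper (background) signals so they
do not become identical.

Everything is seeded and bit-reproducible; ground truth is recorded per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import GenotypeMatrix, HashCounts, HashExpression, ValidationError
from .evaluation import TruthCall, SINGLET, MULTIPLET

logger = logging.getLogger("snacs")


@dataclass
class SimConfig:
    """Study conditions for one simulated multiplexed experiment."""

    S: int = 2                       # number of multiplexed samples
    C: int = 4000                    # total sampled cells
    p: float = 0.10                  # proportion of multiplets
    n_snps: int = 40
    snps_private_per_patient: int = 4
    background_snp_rate: float = 0.25   # per-patient chance of a shared variant
    dropout_rate: float = 0.10
    proper_mean: float = 4.0         # target proper-hash mean, CLR units
    proper_var: float = 1.0          # target proper-hash variance
    background_mean: float = 0.0
    background_var: float = 0.64
    noise_scale: float = 0.5         # improper-hash noise variance, x proper_var
    doublet_mean_shrink: float = 0.20
    doublet_var_inflate: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p must lie in [0, 1]")
        if self.S < 2:
            raise ValidationError("need at least 2 multiplexed samples")
        if self.C < self.S:
            raise ValidationError("C must be >= S")
        if self.n_snps < self.S * self.snps_private_per_patient:
            raise ValidationError(
                "infeasible: n_snps < S * snps_private_per_patient")


@dataclass
class HashMomentModel:
    """Per-hash raw proper-signal moments and the a*H+b adjustment to targets."""

    hash_id: str
    raw_mean: float
    raw_var: float
    a: float
    b: float

    @classmethod
    def fit(cls, hash_id: str, raw_mean: float, raw_var: float,
            target_mean: float, target_var: float) -> "HashMomentModel":
        a = float(np.sqrt(target_var / raw_var))
        b = float(target_mean - a * raw_mean)
        return cls(hash_id, raw_mean, raw_var, a, b)

    def adjust(self, h: np.ndarray) -> np.ndarray:
        return self.a * h + self.b


@dataclass
class PatientProfiles:
    sample_ids: list[str]            # one hash id per patient
    snp_ids: list[str]
    profiles: np.ndarray             # patients x SNPs binary
    moment_models: list[HashMomentModel]


@dataclass
class SyntheticExperiment:
    genotypes: GenotypeMatrix
    expression: HashExpression
    truth: list[TruthCall]
    multiplet_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def truth_by_cell(self) -> dict[str, TruthCall]:
        return {t.cell_id: t for t in self.truth}


def generate_patient_profiles(n_patients: int, cfg: SimConfig,
                              rng: np.random.Generator | None = None
                              ) -> PatientProfiles:
    """Draw per-patient SNP profiles and raw hash moments.

    Each patient receives ``snps_private_per_patient`` private mutated SNPs;
    the remaining SNPs are shared background variants each patient carries
    independently with ``background_snp_rate``.  Raw proper-hash moments vary
    across hashes and are paired with the affine adjustment to the common
    targets.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k = cfg.snps_private_per_patient
    if cfg.n_snps < n_patients * k:
        raise ValidationError("infeasible: not enough SNPs for private blocks")
    snp_ids = [f"snp{j + 1:04d}" for j in range(cfg.n_snps)]
    sample_ids = [f"TS-{i + 1}" for i in range(n_patients)]

    profiles = np.zeros((n_patients, cfg.n_snps), dtype=float)
    for i in range(n_patients):
        profiles[i, i * k:(i + 1) * k] = 1.0
    n_shared = cfg.n_snps - n_patients * k
    if n_shared:
        shared = rng.random((n_patients, n_shared)) < cfg.background_snp_rate
        profiles[:, n_patients * k:] = shared

    models = []
    for i, h in enumerate(sample_ids):
        raw_mean = float(rng.normal(cfg.proper_mean, 0.3))
        raw_var = float(rng.uniform(0.7, 1.3) * cfg.proper_var)
        models.append(HashMomentModel.fit(h, raw_mean, raw_var,
                                          cfg.proper_mean, cfg.proper_var))
    return PatientProfiles(sample_ids, snp_ids, profiles, models)


def merge_variant_pair(g1: float, g2: float) -> float:
    """Combine two cells' calls at one variant into the multiplet call.

    Mutated dominates: any observed 1 gives 1; otherwise 0 (a pair of
    missing calls is emitted as wildtype).  Symmetric in its arguments.
    """
    m1, m2 = np.isnan(g1), np.isnan(g2)
    if (not m1 and g1 == 1) or (not m2 and g2 == 1):
        return 1.0
    return 0.0


def _draw_genotypes(profile: np.ndarray, n: int, cfg: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    g = np.tile(profile, (n, 1)).astype(float)
    if cfg.dropout_rate > 0:
        g[rng.random(g.shape) < cfg.dropout_rate] = np.nan
    return g


def simulate_multiplexed(cfg: SimConfig,
                         profiles: PatientProfiles | None = None
                         ) -> SyntheticExperiment:
    """Sample one multiplexed experiment: singlets, multiplets, hash signals.

    Exactly ``round((1-p)*C)`` singlets and ``round(p*C)`` multiplets are
    produced; multiplet pairs never share a sample of origin.
    """
    rng = np.random.default_rng(cfg.seed)
    if profiles is None:
        profiles = generate_patient_profiles(cfg.S, cfg, rng)
    S = len(profiles.sample_ids)
    n_mult = int(round(cfg.p * cfg.C))
    n_sing = cfg.C - n_mult
    if cfg.p > 0 and n_mult == 0:
        logger.warning("p*C < 1: no multiplets emitted")

    sing_origin = rng.integers(0, S, size=n_sing)
    pair_first = rng.integers(0, S, size=n_mult)
    pair_offset = rng.integers(1, S, size=n_mult)
    pair_second = (pair_first + pair_offset) % S   # never equal to the first

    genotype_rows, expr_rows, cell_ids = [], [], []
    truth: list[TruthCall] = []
    pairs: dict[str, tuple[str, str]] = {}

    bg_sd = float(np.sqrt(cfg.background_var))
    noise_sd = float(np.sqrt(cfg.noise_scale * cfg.proper_var)) if S >= 3 else 0.0

    def improper(n: int) -> np.ndarray:
        vals = rng.normal(cfg.background_mean, bg_sd, size=n)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=n)
        return vals

    def proper(model: HashMomentModel, n: int, doublet: bool) -> np.ndarray:
        raw = rng.normal(model.raw_mean, np.sqrt(model.raw_var), size=n)
        adj = model.adjust(raw)
        if doublet:
            mean = cfg.proper_mean * (1.0 - cfg.doublet_mean_shrink)
            sd = np.sqrt(cfg.proper_var * (1.0 + cfg.doublet_var_inflate))
            adj = (adj - cfg.proper_mean) / np.sqrt(cfg.proper_var) * sd + mean
        return adj

    for idx in range(n_sing):
        i = int(sing_origin[idx])
        cid = f"cell{idx + 1:05d}"
        cell_ids.append(cid)
        genotype_rows.append(_draw_genotypes(profiles.profiles[i], 1, cfg, rng)[0])
        row = improper(S)
        row[i] = proper(profiles.moment_models[i], 1, doublet=False)[0]
        expr_rows.append(row)
        truth.append(TruthCall(cid, SINGLET, profiles.sample_ids[i]))

    for idx in range(n_mult):
        i, j = int(pair_first[idx]), int(pair_second[idx])
        cid = f"cell{n_sing + idx + 1:05d}"
        cell_ids.append(cid)
        g1 = _draw_genotypes(profiles.profiles[i], 1, cfg, rng)[0]
        g2 = _draw_genotypes(profiles.profiles[j], 1, cfg, rng)[0]
        # the merge truth table never emits a missing call
        merged = np.array([merge_variant_pair(a, b) for a, b in zip(g1, g2)])
        genotype_rows.append(merged)
        row = improper(S)
        for origin in (i, j):
            row[origin] = proper(profiles.moment_models[origin], 1, doublet=True)[0]
        expr_rows.append(row)
        truth.append(TruthCall(cid, MULTIPLET))
        pairs[cid] = (profiles.sample_ids[i], profiles.sample_ids[j])

    G = GenotypeMatrix(cell_ids, list(profiles.snp_ids), np.array(genotype_rows))
    E = HashExpression(cell_ids, list(profiles.sample_ids), np.array(expr_rows))
    return SyntheticExperiment(G, E, truth, pairs)


def expression_to_counts(E: HashExpression, scale: float = 100.0,
                         rng: np.random.Generator | None = None) -> HashCounts:
    """Emit integer pseudo-counts whose CLR roughly reproduces ``E``.

    Inverts the per-antibody CLR up to the (unknown) geometric mean by
    treating ``scale`` as that mean: count = round(scale * 2^v) - 1.  Useful
    for end-to-end tests of the count-reading code path.
    """
    counts = np.maximum(np.rint(scale * np.exp2(E.values)) - 1, 0).astype(np.int64)
    return HashCounts(list(E.cell_ids), list(E.hash_ids), counts)


def simulate_allele_depths(exp: SyntheticExperiment, profiles: PatientProfiles,
                           depth: int = 80, seed: int = 0,
                           het_fraction: float = 1.0):
    """Companion allele-depth matrices for the doublet-detection stage.

    Singlets draw alt depth around VAF 0.5 at mutated loci (heterozygous
    calls) and around the error rate elsewhere; multiplets use the mixture
    VAFs 0.25/0.75 at loci where their two source profiles disagree.
    """
    from .doubletd import AlleleDepthMatrix

    rng = np.random.default_rng(seed)
    by_sample = {s: i for i, s in enumerate(profiles.sample_ids)}
    eps = 0.01
    n_cells = len(exp.genotypes.cell_ids)
    n_loci = len(profiles.snp_ids)
    tot = rng.poisson(depth, size=(n_cells, n_loci)).astype(np.int64)
    tot = np.maximum(tot, 1)
    vaf = np.full((n_cells, n_loci), eps)
    truth_by_cell = exp.truth_by_cell()
    for ci, cid in enumerate(exp.genotypes.cell_ids):
        t = truth_by_cell[cid]
        if t.kind == SINGLET:
            prof = profiles.profiles[by_sample[t.sample]]
            vaf[ci, prof == 1] = 0.5 * het_fraction
        else:
            s1, s2 = exp.multiplet_pairs[cid]
            p1 = profiles.profiles[by_sample[s1]]
            p2 = profiles.profiles[by_sample[s2]]
            both = (p1 == 1) & (p2 == 1)
            one = (p1 == 1) ^ (p2 == 1)
            vaf[ci, both] = 0.5
            vaf[ci, one] = 0.25
    alt = rng.binomial(tot, vaf)
    return AlleleDepthMatrix(list(exp.genotypes.cell_ids),
                             list(profiles.snp_ids), tot, alt)
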