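"""Synthetic MAGIC genotypes, trait architectures and replicate studies.

The genotype generator emulates a four-founder multi-parent advanced
generation intercross: founder inbreds are paired into two F1s, the F1s
are intercrossed, and the offspring are selfed by single-seed descent to
near-homozygosity.  Meioses recombine along a clumped genetic map
(tightly linked SNP clumps separated by wide gaps), which produces the
blocky LD structure the block-level model exploits.  A direct
block-correlated generator is available as a fast alternative.

The phenotype architecture places additive effects at 55 SNPs in 10
distinct LD blocks: 5 single-SNP major QTLs (3 with common effects over
both seasons, 2 season-specific) with effects ~ N(5, 1.5²), and 5
ten-SNP minor blocks (3 common, 2 season-specific) with per-SNP effects
~ N(1.5, 0.5²); residuals are N(0, 100) per line and season.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PhenotypeTable
from .ldblocks import LDBlockSet, cluster_ld_blocks
from .model import MCMCConfig, ModelSpec, fit_bayes_b, fit_bayes_c, fit_ldbayes
from .qtl import significant_blocks, significant_snps

#: block-size mix of the clumped map; mirrors a genotyping panel whose LD
#: clusters average ~3.2 SNPs with ~40% singletons and a thin tail of
#: clusters carrying 10+ SNPs
DEFAULT_BLOCK_SIZES = ((1, 0.40), (2, 0.22), (3, 0.14), (4, 0.06),
                       (5, 0.05), (8, 0.04), (10, 0.04), (12, 0.03),
                       (15, 0.02))


@dataclass
class SimDesign:
    """Trait architecture of the simulation study."""

    n_major: int = 5            # single causal SNPs in distinct blocks
    n_major_common: int = 3     # of which common across both seasons
    n_minor_blocks: int = 5     # ten-SNP minor-effect blocks
    n_minor_common: int = 3
    snps_per_minor_block: int = 10
    major_mean: float = 5.0
    major_var: float = 2.25
    minor_mean: float = 1.5
    minor_var: float = 0.25
    residual_var: float = 100.0
    n_seasons: int = 2
    n_replicates: int = 50
    effect_scale: float = 1.0   # multiplies all drawn effects (power sweeps)

    @property
    def n_causal_snps(self) -> int:
        return self.n_major + self.n_minor_blocks * self.snps_per_minor_block


@dataclass
class SimTruth:
    """Causal architecture drawn for one simulated dataset."""

    causal_snps: np.ndarray          # SNP indices, majors first
    causal_blocks: np.ndarray        # block id per causal SNP
    effect_type: list                # "common" or "season<j>" per causal SNP
    effects: np.ndarray              # drawn effect sizes
    qtl_labels: list = field(default_factory=list)  # per distinct block

    def true_block_set(self) -> set:
        return set(int(b) for b in self.causal_blocks)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _clumped_map(n_snps: int, block_size_dist, rng,
                 chrom_cm: float = 150.0, clump_span_cm: float = 0.01):
    """Genetic positions (cM) for one chromosome: clumps of tightly linked
    SNPs spread over ``chrom_cm`` centimorgans."""
    sizes, probs = zip(*block_size_dist)
    clumps = []
    total = 0
    while total < n_snps:
        s = int(rng.choice(sizes, p=np.asarray(probs) / np.sum(probs)))
        s = min(s, n_snps - total)
        clumps.append(s)
        total += s
    starts = np.sort(rng.uniform(0, chrom_cm, size=len(clumps)))
    pos = []
    for start, size in zip(starts, clumps):
        pos.extend(start + np.arange(size) * (clump_span_cm / max(size, 1)))
    return np.asarray(pos), clumps


def _founder_alleles(clumps, n_snps, within_block_r2, rng):
    """Founder haplotypes (4 × n_snps, alleles 0/1): one polymorphic base
    pattern per clump, members jittered so realised pairwise r² within a
    clump stays at or above the target."""
    flip = 0.5 * (1.0 - within_block_r2 ** 0.125)  # (1-2e)^8 >= target^... margin
    H = np.empty((4, n_snps), dtype=np.int8)
    j = 0
    for size in clumps:
        while True:
            base = rng.integers(0, 2, size=4)
            if 0 < base.sum() < 4:
                break
        for _ in range(size):
            while True:
                col = np.where(rng.random(4) < flip, 1 - base, base)
                if 0 < col.sum() < 4:
                    break
            H[:, j] = col
            j += 1
    return H


def _gametes(h1, h2, rec_prob, chrom_ptr, rng):
    """One gamete per individual from haplotype pair (h1, h2): crossover
    states follow per-interval recombination probabilities, with an
    independent random phase per chromosome."""
    n, p = h1.shape
    switch = rng.random((n, p)) < rec_prob[None, :]
    for c in range(len(chrom_ptr) - 1):
        lo = chrom_ptr[c]
        switch[:, lo] = rng.integers(0, 2, size=n).astype(bool)
    state = np.cumsum(switch, axis=1) % 2
    return np.where(state == 0, h1, h2)


def simulate_magic_genotypes(n_lines: int = 256, n_chrom: int = 10,
                             snps_per_chrom: int = 150,
                             block_size_dist=DEFAULT_BLOCK_SIZES,
                             within_block_r2: float = 0.75,
                             seed: int = 0, n_selfing: int = 6,
                             mode: str = "magic") -> GenotypeMatrix:
    """Generate near-homozygous multi-parent RIL genotypes.

    ``mode="magic"`` runs the founder-mosaic pedigree (two F1 crosses,
    one intercross, ``n_selfing`` generations of single-seed descent);
    ``mode="block"`` draws block-correlated ±1 genotypes directly.
    Deterministic per seed.
    """
    if min(n_lines, n_chrom, snps_per_chrom) < 1:
        raise ValueError("dimensions must be positive")
    if max(s for s, _ in block_size_dist) > snps_per_chrom:
        raise ValueError("block size exceeds SNPs per chromosome")
    rng = np.random.default_rng(seed)
    p_total = n_chrom * snps_per_chrom
    cm_pos, chrom_names, chrom_ptr, clumps_all = [], [], [0], []
    for c in range(n_chrom):
        pos, clumps = _clumped_map(snps_per_chrom, block_size_dist, rng)
        cm_pos.append(pos)
        clumps_all.extend(clumps)
        chrom_names.extend([f"chr{c + 1:02d}"] * snps_per_chrom)
        chrom_ptr.append(chrom_ptr[-1] + snps_per_chrom)
    cm_pos = np.concatenate(cm_pos)
    chrom = np.asarray(chrom_names, dtype=object)
    pos_bp = (cm_pos * 1e6).astype(np.int64)  # 1 cM ≈ 1 Mb
    snp_ids = np.asarray([f"snp{j:05d}" for j in range(p_total)], dtype=object)
    lines = [f"line{i:04d}" for i in range(n_lines)]

    if mode == "block":
        calls = np.empty((n_lines, p_total), dtype=np.int8)
        flip = 0.5 * (1.0 - within_block_r2 ** 0.25)
        j = 0
        for size in clumps_all:
            latent = rng.choice([-1, 1], size=n_lines)
            for _ in range(size):
                col = np.where(rng.random(n_lines) < flip, -latent, latent)
                calls[:, j] = col
                j += 1
        calls *= _random_phases(p_total, rng)
        return GenotypeMatrix(lines, snp_ids, chrom, pos_bp, calls).sort_snps()
    if mode != "magic":
        raise ValueError(f"unknown generator mode {mode!r}")

    # per-interval recombination (Haldane) from cM distances; 0 across chroms
    d = np.diff(cm_pos, prepend=cm_pos[0])
    rec = 0.5 * (1.0 - np.exp(-2.0 * np.clip(d, 0, None) / 100.0))
    rec[0] = 0.0
    for c in range(n_chrom):
        rec[chrom_ptr[c]] = 0.0

    H = _founder_alleles(clumps_all, p_total, within_block_r2, rng)
    tile = lambda h: np.tile(h, (n_lines, 1))
    # F1s of the two founder pairs are (A,B) and (C,D); the intercross
    # offspring take one recombined gamete from each F1
    h1 = _gametes(tile(H[0]), tile(H[1]), rec, chrom_ptr, rng)
    h2 = _gametes(tile(H[2]), tile(H[3]), rec, chrom_ptr, rng)
    for _ in range(n_selfing):
        h1, h2 = (_gametes(h1, h2, rec, chrom_ptr, rng),
                  _gametes(h1, h2, rec, chrom_ptr, rng))
    calls = (h1 + h2 - 1).astype(np.int8)
    # allele labels (which homozygote is coded -1) are arbitrary per SNP,
    # as in real biallelic calling; randomise the phase
    calls *= _random_phases(p_total, rng)
    return GenotypeMatrix(lines, snp_ids, chrom, pos_bp, calls).sort_snps()


def _random_phases(p: int, rng) -> np.ndarray:
    return rng.choice(np.array([-1, 1], dtype=np.int8), size=p)[None, :]


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def draw_architecture(blocks: LDBlockSet, design: SimDesign,
                      seed: int) -> SimTruth:
    """Draw the causal architecture: host blocks, causal member SNPs and
    effect sizes — the fixed truth of one simulation study.

    Majors (single causal SNPs, listed first) are drawn over all blocks,
    minors over blocks with enough members; season-specific QTLs
    alternate over seasons.  Effects: N(major_mean, major_var) and
    N(minor_mean, minor_var), times ``effect_scale``.
    """
    rng = np.random.default_rng(seed)
    sizes = blocks.sizes()
    eligible_minor = np.flatnonzero(sizes >= design.snps_per_minor_block)
    if len(eligible_minor) < design.n_minor_blocks:
        raise ValueError(
            f"only {len(eligible_minor)} blocks can host "
            f"{design.snps_per_minor_block}-SNP minor groups")
    minor_blocks = rng.choice(eligible_minor, size=design.n_minor_blocks,
                              replace=False)
    remaining = np.setdiff1d(np.arange(blocks.n_blocks), minor_blocks)
    major_blocks = rng.choice(remaining, size=design.n_major, replace=False)

    causal_snps, causal_blocks, etypes, labels = [], [], [], []
    m = design.n_seasons
    season_rr = 0
    for t, b in enumerate(major_blocks):
        causal_snps.append(int(rng.choice(blocks.members(b))))
        causal_blocks.append(int(b))
        if t < design.n_major_common:
            etypes.append("common")
            labels.append(f"major_common_{t + 1}")
        else:
            season = season_rr % m + 1
            season_rr += 1
            etypes.append(f"season{season}")
            labels.append(f"major_gxe_{t - design.n_major_common + 1}")
    season_rr = 0
    for t, b in enumerate(minor_blocks):
        snps = rng.choice(blocks.members(b), size=design.snps_per_minor_block,
                          replace=False)
        if t < design.n_minor_common:
            etype, label = "common", f"minor_common_{t + 1}"
        else:
            season = season_rr % m + 1
            season_rr += 1
            etype = f"season{season}"
            label = f"minor_gxe_{t - design.n_minor_common + 1}"
        labels.append(label)
        for snp in snps:
            causal_snps.append(int(snp))
            causal_blocks.append(int(b))
            etypes.append(etype)
    causal_snps = np.asarray(causal_snps)
    n_causal = len(causal_snps)
    effects = np.empty(n_causal)
    sd_major = np.sqrt(design.major_var)
    sd_minor = np.sqrt(design.minor_var)
    for t in range(n_causal):
        if t < design.n_major:
            effects[t] = rng.normal(design.major_mean, sd_major)
        else:
            effects[t] = rng.normal(design.minor_mean, sd_minor)
    effects *= design.effect_scale
    return SimTruth(causal_snps, np.asarray(causal_blocks), etypes,
                    effects, labels)


def simulate_phenotypes(g: GenotypeMatrix, blocks: LDBlockSet,
                        design: Optional[SimDesign] = None,
                        seed: int = 0, truth: Optional[SimTruth] = None):
    """Simulate the two-season trait on top of a genotype/block set.

    ``truth`` (from :func:`draw_architecture`) may be supplied to keep
    the causal architecture fixed while redrawing residuals only; by
    default a fresh architecture is drawn from ``seed``.  Returns
    (PhenotypeTable, SimTruth).
    """
    design = design or SimDesign()
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = draw_architecture(blocks, design, seed)
    causal_snps, etypes, effects = (truth.causal_snps, truth.effect_type,
                                    truth.effects)
    m = design.n_seasons
    X = g.calls[:, causal_snps].astype(float)
    y = np.zeros((g.n_lines, m))
    for j in range(m):
        active = np.array([e == "common" or e == f"season{j + 1}"
                           for e in etypes])
        y[:, j] = X[:, active] @ effects[active]
    y += rng.normal(0.0, np.sqrt(design.residual_var), size=y.shape)

    records = []
    for j in range(m):
        for i, line in enumerate(g.lines):
            records.append((line, j + 1, "sim", y[i, j]))
    pheno = PhenotypeTable(pd.DataFrame(
        records, columns=["line", "env", "trait", "value"]))
    return pheno, truth


# ---------------------------------------------------------------------------
# replicate study
# ---------------------------------------------------------------------------

@dataclass
class ReplicateStudyResult:
    detection: pd.DataFrame          # per QTL label × method: frequency
    false_positives: pd.DataFrame    # per method: mean FP per replicate
    accuracies: Optional[pd.DataFrame]
    n_reps: int

    def high_confidence_counts(self, role: str, method: str,
                               threshold: float = 0.5) -> int:
        """QTLs of a role ("major"/"minor") detected at frequency above
        the high-confidence threshold."""
        det = self.detection
        sub = det[det["label"].str.startswith(role)]
        return int((sub[method] > threshold).sum())


def _detected_blocks_ldbayes(fit, bf_threshold):
    hits = set(significant_blocks(fit, bf_threshold))
    if fit.gamma_gxe is not None:
        for j in range(1, fit.m + 1):
            hits |= set(significant_blocks(fit, bf_threshold, env=j))
    return hits


def run_replicate_study(design: Optional[SimDesign] = None,
                        methods=("ldbayes", "bayesb", "bayesc"),
                        mcmc: Optional[MCMCConfig] = None,
                        n_reps: Optional[int] = None,
                        bf_threshold: float = 100.0,
                        seed: int = 0,
                        n_lines: int = 256, n_chrom: int = 10,
                        snps_per_chrom: int = 150,
                        genotype_mode: str = "magic",
                        spec: Optional[ModelSpec] = None,
                        cv_folds: int = 0) -> ReplicateStudyResult:
    """Replicate simulation study of QTL detection and false positives.

    One genotype panel, its LD blocks and one causal architecture
    (placement and effect sizes) are drawn per study seed; each
    replicate redraws only the residual noise, fits the requested
    methods, and declares significance at
    ``bf_threshold`` (block-level Bayes factors for the LD-aware model,
    per-SNP Bayes factors for Bayes B/C, credited to the true block the
    SNP falls in).  A significant call outside every true block counts
    as a false positive.  With ``cv_folds > 0`` a per-replicate
    prediction-accuracy comparison (train season 1, test season 2) is
    added.  Bit-reproducible given ``seed``.
    """
    from .prediction import cv_accuracy

    design = design or SimDesign()
    mcmc = mcmc or MCMCConfig(n_iter=2000, burn_in=500, thin=3, seed=seed)
    n_reps = n_reps if n_reps is not None else design.n_replicates
    spec = spec or ModelSpec()
    g = simulate_magic_genotypes(n_lines, n_chrom, snps_per_chrom,
                                 seed=seed, mode=genotype_mode)
    blocks = cluster_ld_blocks(g)
    # causal architecture (placement and effect sizes) fixed for the
    # whole study; replicates redraw residuals only
    truth = draw_architecture(blocks, design, seed)

    detect_methods = [m_ for m_ in methods if m_ != "gblup"]
    labels = None
    det_counts: dict = {}
    fp_counts = {meth: [] for meth in detect_methods}
    acc_rows = []
    meth_offset = {"ldbayes": 0, "bayesb": 100, "bayesc": 200, "gblup": 300}
    for rep in range(n_reps):
        rep_seed = (seed + 1) * 10_000 + rep
        pheno, _ = simulate_phenotypes(g, blocks, design, seed=rep_seed,
                                       truth=truth)
        if labels is None:
            labels = list(truth.qtl_labels)
            det_counts = {meth: {lab: 0 for lab in labels}
                          for meth in detect_methods}
        true_blocks = truth.true_block_set()
        block_of_label = _label_blocks(truth, design)
        for meth in detect_methods:
            rng_mcmc = MCMCConfig(mcmc.n_iter, mcmc.burn_in, mcmc.thin,
                                  seed=rep_seed + meth_offset[meth])
            if meth == "ldbayes":
                fit = fit_ldbayes(g, pheno, blocks, spec, rng_mcmc)
                hits = _detected_blocks_ldbayes(fit, bf_threshold)
                fp = len(hits - true_blocks)
            elif meth in ("bayesb", "bayesc"):
                # the single-environment fitters analyse across-season
                # line means (their standard usage); per-SNP calls are
                # credited to the host block.  They are cheap per sweep,
                # so they get a longer schedule than the block model.
                fitter = fit_bayes_b if meth == "bayesb" else fit_bayes_c
                y_mean = pheno.trait_matrix("sim", list(g.lines)).mean(axis=1)
                fit = fitter(g, y_mean,
                             MCMCConfig(3 * mcmc.n_iter, 3 * mcmc.burn_in,
                                        3 * mcmc.thin, seed=rng_mcmc.seed),
                             spec)
                hits = set()
                fp = 0
                for snp in significant_snps(fit, bf_threshold):
                    b = int(blocks.snp_to_block[snp])
                    if b in true_blocks:
                        hits.add(b)
                    else:
                        fp += 1
            else:
                raise ValueError(f"unknown method {meth!r}")
            fp_counts[meth].append(fp)
            for lab, b in block_of_label.items():
                if b in hits:
                    det_counts[meth][lab] += 1
        if cv_folds > 0:
            for meth in methods:
                acc, _ = cv_accuracy(
                    g, pheno, blocks, spec, mcmc, folds=cv_folds,
                    seed=rep_seed, method=meth,
                    train_envs=[1], test_env=2)
                acc_rows.append({"rep": rep, "method": meth, "accuracy": acc})

    detection = pd.DataFrame({
        "label": labels,
        **{meth: [det_counts[meth][lab] / n_reps for lab in labels]
           for meth in detect_methods}})
    fps = pd.DataFrame({
        "method": detect_methods,
        "mean_false_positives": [float(np.mean(fp_counts[m_]))
                                 for m_ in detect_methods],
    })
    acc = pd.DataFrame(acc_rows) if acc_rows else None
    return ReplicateStudyResult(detection, fps, acc, n_reps)


def _label_blocks(truth: SimTruth, design: SimDesign) -> dict:
    """Map each QTL label to its (single) causal block id."""
    out = {}
    # majors occupy the first n_major causal entries, one SNP each
    for t in range(design.n_major):
        out[truth.qtl_labels[t]] = int(truth.causal_blocks[t])
    off = design.n_major
    for t in range(design.n_minor_blocks):
        lab = truth.qtl_labels[design.n_major + t]
        out[lab] = int(truth.causal_blocks[off])
        off += design.snps_per_minor_block
    return out
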