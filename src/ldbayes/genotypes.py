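"""Genotype and phenotype containers, readers, filtering, and imputation.

Genotypes are biallelic SNP calls over inbred-line panels, coded
``-1`` (AA), ``0`` (AB), ``1`` (BB); missing cells use :data:`MISSING`.
Phenotypes are long-format ``(line, environment, trait, value)`` records,
typically adjusted line means from replicated multi-environment trials.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in the int8 call matrix.
MISSING: int = -9

_LETTER_CODES = {
    "AA": -1, "AB": 0, "BA": 0, "BB": 1,
    "-1": -1, "0": 0, "1": 1,
    "NA": MISSING, "NAN": MISSING, ".": MISSING, "": MISSING, "./.": MISSING,
}


class GenotypeError(ValueError):
    """Malformed or invariant-violating genotype input."""


@dataclass
class GenotypeMatrix:
    """Lines × SNPs call matrix with per-SNP chromosome/position metadata.

    Attributes
    ----------
    lines : list of str
        Ordered, unique line identifiers (rows of ``calls``).
    snp_ids : ndarray of str
        Ordered, unique SNP identifiers (columns of ``calls``).
    chrom : ndarray of str
        Chromosome name per SNP.
    pos : ndarray of int
        Physical position (bp) per SNP; non-negative.
    calls : ndarray of int8, shape (n_lines, n_snps)
        Values in {-1, 0, 1, MISSING}.
    """

    lines: list
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.calls.shape
        if len(self.lines) != n:
            raise GenotypeError(f"{len(self.lines)} line ids for {n} call rows")
        for name, arr in (("snp_ids", self.snp_ids), ("chrom", self.chrom),
                          ("pos", self.pos)):
            if len(arr) != p:
                raise GenotypeError(f"{name} has {len(arr)} entries for {p} SNPs")
        if len(set(self.lines)) != n:
            raise GenotypeError("duplicated line ids")
        if len(set(self.snp_ids)) != p:
            dup = pd.Series(self.snp_ids)[pd.Series(self.snp_ids).duplicated()]
            raise GenotypeError(f"duplicated SNP ids: {sorted(set(dup))[:5]}")
        if np.any(self.pos < 0):
            raise GenotypeError("negative SNP positions")
        bad = ~np.isin(self.calls, (-1, 0, 1, MISSING))
        if bad.any():
            raise GenotypeError(f"invalid call values {np.unique(self.calls[bad])}")

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency.

        -1/1 count as two copies of the respective allele, 0 as one of
        each; missing cells are excluded from the denominator.  SNPs with
        all calls missing get MAF 0.
        """
        obs = self.calls != MISSING
        calls = np.where(obs, self.calls, 0).astype(np.float64)
        # copies of the "1" allele: (-1 -> 0, 0 -> 1, 1 -> 2)
        alt = ((calls + 1) * obs).sum(axis=0)
        tot = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.where(tot > 0, alt / tot, 0.0)
        return np.minimum(p1, 1.0 - p1)

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.lines, self.snp_ids[idx], self.chrom[idx],
                              self.pos[idx], self.calls[:, idx])

    def subset_lines(self, which) -> "GenotypeMatrix":
        """Subset by line ids or integer indices (order preserved)."""
        if len(which) and isinstance(which[0], str):
            lut = {l: i for i, l in enumerate(self.lines)}
            idx = np.array([lut[w] for w in which])
        else:
            idx = np.asarray(which)
        return GenotypeMatrix([self.lines[i] for i in idx], self.snp_ids,
                              self.chrom, self.pos, self.calls[idx, :])

    def dosage(self) -> np.ndarray:
        """Calls as float64 with missing mapped to NaN."""
        x = self.calls.astype(np.float64)
        x[self.calls == MISSING] = np.nan
        return x

    def sort_snps(self) -> "GenotypeMatrix":
        """Deterministic (chromosome, position, id) SNP ordering."""
        order = np.lexsort((self.snp_ids.astype(str),
                            self.pos, self.chrom.astype(str)))
        return self.subset_snps(order)


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: one value per (line, env, trait).

    Environments are coded 1..m.  Backed by a pandas DataFrame with
    columns ``line``, ``env``, ``trait``, ``value``.
    """

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        req = {"line", "env", "trait", "value"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"phenotype table needs columns {sorted(req)}")
        self.data = self.data.copy()
        self.data["env"] = self.data["env"].astype(int)
        self.data["value"] = self.data["value"].astype(float)
        if self.data.duplicated(["line", "env", "trait"]).any():
            raise ValueError("more than one value per (line, env, trait)")
        envs = sorted(self.data["env"].unique())
        if envs != list(range(1, len(envs) + 1)):
            raise ValueError(f"environments must be 1..m, got {envs}")

    @property
    def environments(self) -> list:
        return sorted(self.data["env"].unique())

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique())

    def trait_matrix(self, trait: str, lines: list) -> np.ndarray:
        """(n_lines, m) value matrix for one trait; NaN where unobserved."""
        sub = self.data[self.data["trait"] == trait]
        m = len(self.environments)
        out = np.full((len(lines), m), np.nan)
        lut = {l: i for i, l in enumerate(lines)}
        for line, env, val in zip(sub["line"], sub["env"], sub["value"]):
            if line in lut:
                out[lut[line], env - 1] = val
        return out

    def subset_envs(self, envs) -> "PhenotypeTable":
        """Keep the listed environments, renumbered 1..len(envs) in order."""
        remap = {e: i + 1 for i, e in enumerate(envs)}
        sub = self.data[self.data["env"].isin(envs)].copy()
        sub["env"] = sub["env"].map(remap)
        return PhenotypeTable(sub, self.units)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _code_cell(raw, snp: str, line: str) -> int:
    token = str(raw).strip().upper()
    if token in _LETTER_CODES:
        return _LETTER_CODES[token]
    try:
        val = int(float(token))
    except ValueError:
        raise GenotypeError(
            f"uninterpretable call {raw!r} at SNP {snp}, line {line}")
    if val in (-1, 0, 1):
        return val
    raise GenotypeError(f"call {raw!r} at SNP {snp}, line {line} not in -1/0/1")


def read_genotype_table(path, map_path=None, sep=None) -> GenotypeMatrix:
    """Read a delimited genotype table (header of SNP ids, first column line id).

    Calls may be numeric (-1/0/1) or letter-coded (AA/AB/BB); NA/./-empty are
    missing.  ``map_path`` is an optional SNP-map file with columns
    (snp_id, chrom, pos_bp); without it all SNPs go on chromosome "1" at
    positions 0,1,2,...  SNPs are returned in (chrom, pos, id) order.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise GenotypeError(f"{path}: expected line-id column plus SNP columns")
    line_col = df.columns[0]
    lines = df[line_col].tolist()
    snp_ids = np.asarray(df.columns[1:], dtype=object)
    calls = np.empty((len(lines), len(snp_ids)), dtype=np.int8)
    for j, sid in enumerate(snp_ids):
        col = df.iloc[:, j + 1]
        for i, raw in enumerate(col):
            calls[i, j] = _code_cell(raw, sid, lines[i])
    if map_path is not None:
        mp = pd.read_csv(map_path, sep=sep, engine="python")
        mp.columns = [c.lower() for c in mp.columns]
        mp = mp.set_index(mp.columns[0])
        missing_map = [s for s in snp_ids if s not in mp.index]
        if missing_map:
            raise GenotypeError(f"SNP map lacks entries for {missing_map[:5]}")
        chrom = np.asarray([str(mp.loc[s].iloc[0]) for s in snp_ids], dtype=object)
        pos = np.asarray([int(mp.loc[s].iloc[1]) for s in snp_ids])
    else:
        chrom = np.asarray(["1"] * len(snp_ids), dtype=object)
        pos = np.arange(len(snp_ids))
    return GenotypeMatrix(lines, snp_ids, chrom, pos, calls).sort_snps()


def write_genotype_table(g: GenotypeMatrix, path, map_path=None, sep="\t") -> None:
    """Write a genotype table (and optional SNP map) readable by
    :func:`read_genotype_table`; round-trips calls and metadata exactly."""
    df = pd.DataFrame(g.calls.astype(int), index=g.lines,
                      columns=g.snp_ids.astype(str))
    df = df.replace(MISSING, "NA")
    df.index.name = "line"
    df.to_csv(path, sep=sep)
    if map_path is not None:
        pd.DataFrame({"snp_id": g.snp_ids.astype(str),
                      "chrom": g.chrom.astype(str),
                      "pos_bp": g.pos}).to_csv(map_path, sep=sep, index=False)


def read_vcf(path, strict: bool = False) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF (v4.x) via cyvcf2.

    Diploid GTs map hom-ref → -1, het → 0, hom-alt → 1, ./. → missing.
    Multi-allelic sites are skipped with a warning, or rejected when
    ``strict`` is true.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    snp_ids, chrom, pos, cols = [], [], [], []
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            msg = f"non-biallelic site {var.CHROM}:{var.POS}"
            if strict:
                raise GenotypeError(msg)
            logger.warning("skipping %s", msg)
            continue
        gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.full(len(lines), MISSING, dtype=np.int8)
        col[gt == 0] = -1
        col[gt == 1] = 0
        col[gt == 3] = 1
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(int(var.POS))
        cols.append(col)
    if not cols:
        raise GenotypeError(f"{path}: no biallelic SNPs")
    calls = np.stack(cols, axis=1)
    return GenotypeMatrix(lines, np.asarray(snp_ids, dtype=object),
                          np.asarray(chrom, dtype=object),
                          np.asarray(pos), calls).sort_snps()


def read_genotypes(path, format: str = "table", **kw) -> GenotypeMatrix:
    """Dispatching reader: ``format`` in {"vcf", "table"}."""
    if format == "vcf":
        return read_vcf(path, **kw)
    if format == "table":
        return read_genotype_table(path, **kw)
    raise ValueError(f"unknown genotype format {format!r}")


def read_phenotypes(path, sep=None) -> PhenotypeTable:
    """Read a phenotype CSV with columns (line, env, trait, value)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.lower() for c in df.columns]
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path) -> None:
    p.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# filtering / imputation
# ---------------------------------------------------------------------------

def filter_snps(g: GenotypeMatrix, max_missing: float = 0.20,
                min_maf: float = 0.025):
    """Drop SNPs with missing rate > ``max_missing`` or MAF < ``min_maf``.

    Missingness is applied first; MAF is then computed on the remaining
    observed calls.  Returns ``(filtered, removal_log)`` where the log is a
    DataFrame of removed SNPs with the reason.  Idempotent; order preserved.
    """
    if not (0 < max_missing < 1 and 0 < min_maf < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    miss = g.missing_rate()
    maf = g.maf()
    drop_miss = miss > max_missing
    drop_maf = (~drop_miss) & (maf < min_maf)
    keep = ~(drop_miss | drop_maf)
    reasons = np.where(drop_miss, "missing_rate", np.where(drop_maf, "maf", ""))
    log = pd.DataFrame({
        "snp_id": g.snp_ids[~keep].astype(str),
        "reason": reasons[~keep],
        "missing_rate": miss[~keep],
        "maf": maf[~keep],
    })
    if not keep.any():
        warnings.warn("all SNPs removed by filtering")
    return g.subset_snps(np.flatnonzero(keep)), log


def impute_missing(g: GenotypeMatrix, method: str = "mode",
                   seed: int = 0) -> GenotypeMatrix:
    """Fill missing calls per SNP.

    ``mode``: most frequent observed call, ties to the numerically smaller
    code. ``frequency_sample``: draw from the per-SNP empirical call
    distribution (seeded).  Observed calls are never altered.
    """
    if method not in ("mode", "frequency_sample"):
        raise ValueError(f"unknown imputation method {method!r}")
    rng = np.random.default_rng(seed)
    calls = g.calls.copy()
    codes = np.array([-1, 0, 1], dtype=np.int8)
    for j in range(g.n_snps):
        col = calls[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise GenotypeError(
                f"SNP {g.snp_ids[j]} has no observed calls; filter it first")
        counts = np.array([(obs == c).sum() for c in codes])
        if method == "mode":
            fill = codes[np.argmax(counts)]  # argmax takes first ⇒ lower code
            col[miss] = fill
        else:
            probs = counts / counts.sum()
            col[miss] = rng.choice(codes, size=miss.sum(), p=probs)
    return GenotypeMatrix(g.lines, g.snp_ids, g.chrom, g.pos, calls)
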