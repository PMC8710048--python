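"""Quantitative genetics downstream of leaf-angle phenotyping.

Covers the analysis chain applied to per-leaf angle tables: median
aggregation across timepoints and leaves, broad-sense heritability from
a one-way random-effects model, BLUP-based outlier screening, marker
quality filters, Bonferroni significance thresholds, and a
resampling-stability (RMIP) wrapper around a pluggable per-marker
association engine.

Heritability uses the estimator

    H^2 = sigma2_G / (sigma2_G + sigma2_e / 2)

with variance components from the REML fit of ``y_i = mu + t_i + e_i``
(genotype as random effect).  The residual divisor is a fixed 2 —
reflecting that phenotypes are medians of repeated measurements — and
is applied regardless of the realized replicate counts; see the methods
note for discussion.

The built-in linear-model engine is plumbing for simulation studies and
small panels: real GWAS should plug in a dedicated mixed-model or
multi-locus engine through the same interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

PHENOTYPE_COLUMNS = ("plant_id", "genotype_id", "timepoint", "leaf_index", "angle_deg")


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format phenotype table: required columns, angle
    range, uniqueness of (plant, timepoint, leaf)."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    ang = df["angle_deg"].dropna()
    if ((ang < 0) | (ang > 180)).any():
        raise ValueError("angle_deg outside [0, 180]")
    if df.duplicated(subset=["plant_id", "timepoint", "leaf_index"]).any():
        raise ValueError("duplicate (plant, timepoint, leaf) rows")
    return df


# ----------------------------------------------------------------------
# aggregation
# ----------------------------------------------------------------------
def aggregate_angles(
    table: pd.DataFrame,
    leaves: list[int] | None = None,
    timepoints: list | None = None,
) -> pd.DataFrame:
    """Per-plant aggregate angle: median across timepoints within each
    leaf, then median across the requested leaves.

    Returns a frame indexed by plant with columns ``genotype_id``,
    ``angle_deg`` and ``n_cells`` (leaf/timepoint cells used).  Plants
    with no requested data are excluded with a warning.
    """
    df = table.copy()
    if leaves is not None:
        df = df[df["leaf_index"].isin(leaves)]
    if timepoints is not None:
        df = df[df["timepoint"].isin(timepoints)]
    if df.empty:
        raise ValueError("no data for the requested leaves/timepoints")
    per_leaf = (
        df.groupby(["plant_id", "genotype_id", "leaf_index"])["angle_deg"].median().reset_index()
    )
    out = (
        per_leaf.groupby(["plant_id", "genotype_id"])["angle_deg"]
        .agg(["median", "count"])
        .reset_index()
        .rename(columns={"median": "angle_deg", "count": "n_leaves"})
    )
    n_cells = df.groupby("plant_id")["angle_deg"].count()
    out["n_cells"] = out["plant_id"].map(n_cells)
    dropped = set(table["plant_id"]) - set(out["plant_id"])
    if dropped:
        warnings.warn(f"{len(dropped)} plant(s) had no data for the requested cells")
    return out.set_index("plant_id")


# ----------------------------------------------------------------------
# heritability / BLUP
# ----------------------------------------------------------------------
@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_e: float
    n_genotypes: int
    n_obs: int
    method: str = "reml"
    grand_mean: float = 0.0


def _anova_components(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments (one-way ANOVA) variance components; the
    between-group divisor uses the unbalanced-design effective
    replicate number n0 = (N - sum(n_i^2)/N) / (k - 1)."""
    df = pd.DataFrame({"y": values, "g": groups})
    k = df["g"].nunique()
    n = len(df)
    ni = df.groupby("g").size().to_numpy(dtype=float)
    means = df.groupby("g")["y"].mean()
    grand = df["y"].mean()
    sse = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    ssb = float((ni * (means.to_numpy() - grand) ** 2).sum())
    mse = sse / max(n - k, 1)
    msb = ssb / max(k - 1, 1)
    n0 = (n - (ni**2).sum() / n) / max(k - 1, 1)
    s2g = max((msb - mse) / n0, 0.0)
    return s2g, mse, grand


def fit_variance_components(
    table: pd.DataFrame,
    value_col: str = "angle_deg",
    group_col: str = "genotype_id",
    reml_tol: float = 1e-8,
    max_iter: int = 200,
) -> VarianceComponents:
    """REML variance components of the one-way random-effects model
    ``y = mu + genotype + e`` via statsmodels MixedLM, with a
    method-of-moments fallback if the fit does not converge."""
    df = table[[group_col, value_col]].dropna()
    counts = df.groupby(group_col).size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 genotypes with >= 2 replicates")
    y = df[value_col].to_numpy(dtype=float)
    g = df[group_col].to_numpy()
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, np.ones((len(y), 1)), groups=g)
            res = model.fit(reml=True, maxiter=max_iter)
        s2g = float(np.asarray(res.cov_re)[0, 0])
        s2e = float(res.scale)
        grand = float(np.asarray(res.fe_params)[0])
        if not res.converged or not np.isfinite(s2g) or not np.isfinite(s2e):
            raise RuntimeError("REML did not converge")
        method = "reml"
    except Exception:
        s2g, s2e, grand = _anova_components(y, g)
        method = "mom"
    return VarianceComponents(
        sigma2_G=max(s2g, 0.0),
        sigma2_e=max(s2e, 0.0),
        n_genotypes=int(counts.size),
        n_obs=int(len(df)),
        method=method,
        grand_mean=grand,
    )


def heritability(
    table: pd.DataFrame,
    value_col: str = "angle_deg",
    group_col: str = "genotype_id",
) -> tuple[float, VarianceComponents]:
    """Broad-sense heritability H^2 = s2G / (s2G + s2e / 2) from the
    replicated genotypes in the table."""
    vc = fit_variance_components(table, value_col=value_col, group_col=group_col)
    denom = vc.sigma2_G + vc.sigma2_e / 2.0
    if denom <= 0:
        raise ValueError("zero total variance; heritability undefined")
    return vc.sigma2_G / denom, vc


@dataclass
class BlupScreenResult:
    blups: pd.Series  # per-genotype shrunken effects (deviation from mean)
    removed: list  # genotype ids failing the 5-SD screen
    kept: pd.DataFrame  # input table without removed genotypes
    components: VarianceComponents
    n_sd: float = 5.0


def blup_outlier_screen(
    table: pd.DataFrame,
    value_col: str = "angle_deg",
    group_col: str = "genotype_id",
    n_sd: float = 5.0,
) -> BlupScreenResult:
    """Shrunken genotype effects and a single-pass outlier screen.

    The BLUP of genotype i is its centered mean shrunk by
    ``s2G / (s2G + s2e / n_i)``; genotypes whose BLUP lies more than
    ``n_sd`` (default 5) standard deviations from the mean BLUP are
    removed.  The screen is applied once, without re-iteration.
    """
    vc = fit_variance_components(table, value_col=value_col, group_col=group_col)
    df = table[[group_col, value_col]].dropna()
    means = df.groupby(group_col)[value_col].mean()
    ni = df.groupby(group_col).size()
    shrink = vc.sigma2_G / (vc.sigma2_G + vc.sigma2_e / ni)
    blups = shrink * (means - vc.grand_mean)
    sd = float(blups.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        removed = []
    else:
        removed = blups.index[np.abs(blups - blups.mean()) > n_sd * sd].tolist()
    if len(removed) == len(blups):
        raise ValueError("outlier screen removed every genotype")
    kept = table[~table[group_col].isin(removed)].copy()
    return BlupScreenResult(blups=blups, removed=removed, kept=kept, components=vc, n_sd=n_sd)


# ----------------------------------------------------------------------
# markers
# ----------------------------------------------------------------------
@dataclass
class GenotypeMatrix:
    """Marker dosages: (n_markers, n_genotypes) float array with calls in
    {0, 1, 2} and NaN for missing, plus marker metadata."""

    calls: np.ndarray
    marker_ids: list[str]
    genotype_ids: list[str]
    chrom: list | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.marker_ids), len(self.genotype_ids)):
            raise ValueError("calls shape must be (n_markers, n_genotypes)")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("calls must be 0/1/2 or NaN")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(self.calls, axis=1) / 2.0
        return np.minimum(f, 1.0 - f)

    def het(self) -> np.ndarray:
        """Fraction of heterozygous (dosage 1) calls per marker."""
        calls = self.calls
        n = np.sum(~np.isnan(calls), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, np.nansum(calls == 1.0, axis=1) / n, np.nan)

    def subset_genotypes(self, ids_or_idx) -> "GenotypeMatrix":
        idx = (
            np.asarray(ids_or_idx, dtype=int)
            if np.issubdtype(np.asarray(ids_or_idx).dtype, np.integer)
            else np.array([self.genotype_ids.index(i) for i in ids_or_idx])
        )
        return GenotypeMatrix(
            calls=self.calls[:, idx],
            marker_ids=self.marker_ids,
            genotype_ids=[self.genotype_ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            calls=self.calls[mask],
            marker_ids=[m for m, k in zip(self.marker_ids, mask) if k]
            if mask.dtype == bool
            else [self.marker_ids[i] for i in mask],
            genotype_ids=self.genotype_ids,
            chrom=None
            if self.chrom is None
            else ([c for c, k in zip(self.chrom, mask) if k] if mask.dtype == bool else [self.chrom[i] for i in mask]),
            pos=None if self.pos is None else self.pos[mask],
        )


def filter_markers(
    g: GenotypeMatrix, maf_min: float = 0.05, het_max: float = 0.05
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep markers with MAF >= maf_min and heterozygosity <= het_max
    (computed on non-missing calls; all-missing markers are dropped).
    Returns the filtered matrix and a per-marker log of the decision."""
    maf = g.maf()
    het = g.het()
    all_missing = np.isnan(maf)
    keep = ~all_missing & (maf >= maf_min) & (het <= het_max)
    reason = np.where(
        all_missing,
        "all-missing",
        np.where(maf < maf_min, "low-maf", np.where(het > het_max, "high-het", "kept")),
    )
    log = pd.DataFrame({"marker": g.marker_ids, "maf": maf, "het": het, "reason": reason})
    return g.subset_markers(keep), log


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ----------------------------------------------------------------------
# association engine + RMIP
# ----------------------------------------------------------------------
def genotype_pcs(g: GenotypeMatrix, n_pcs: int = 3) -> np.ndarray:
    """Principal components of the genotypes computed from standardized,
    mean-imputed marker dosages; (n_genotypes, n_pcs)."""
    x = g.calls.copy()
    mu = np.nanmean(x, axis=1, keepdims=True)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mu[:, 0], inds[0])
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    u, s, vt = np.linalg.svd(x.T @ x / max(g.n_markers, 1))
    return u[:, :n_pcs] * np.sqrt(s[:n_pcs])


def association_engine_lm(
    phenos: np.ndarray,
    g: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    n_pcs: int = 0,
) -> np.ndarray:
    """Single-marker additive linear-model p-values.

    Per marker, the score test of the additive dosage term in
    ``y ~ 1 + covariates + dosage`` (missing dosages mean-imputed per
    marker).  ``n_pcs`` > 0 adds that many genotype-matrix principal
    components as covariates.  Markers constant in the tested subset get
    p = 1.  Vectorized across markers; intended as plumbing for
    simulation and resampling studies.
    """
    y = np.asarray(phenos, dtype=float)
    if len(y) != g.n_genotypes:
        raise ValueError("phenotype length must equal genotype count")
    if len(y) < 10:
        raise ValueError("need >= 10 genotypes")
    x = g.calls.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(x, axis=1, keepdims=True)
    mu = np.nan_to_num(mu)  # all-missing markers become constant (p = 1)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mu[:, 0], inds[0])

    cov = [np.ones((len(y), 1))]
    if covariates is not None:
        cov.append(np.asarray(covariates, dtype=float).reshape(len(y), -1))
    if n_pcs > 0:
        cov.append(genotype_pcs(g, n_pcs))
    c = np.concatenate(cov, axis=1)
    q, _ = np.linalg.qr(c)
    ry = y - q @ (q.T @ y)
    rx = x - (x @ q) @ q.T
    df = len(y) - c.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough genotypes for the covariate set")
    sxx = (rx**2).sum(axis=1)
    syy = float((ry**2).sum())
    sxy = rx @ ry
    p = np.ones(g.n_markers)
    ok = (sxx > 1e-12) & (syy > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ok, sxy**2 / np.maximum(sxx * syy, 1e-300), 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        t2 = r2 * df / (1.0 - r2)
    p[ok] = stats.f.sf(t2[ok], 1, df)
    return p


@dataclass
class RmipResult:
    counts: pd.Series  # hits per marker across completed runs
    n_runs: int  # completed runs
    n_failed: int
    stable_markers: list
    per_run_alpha: float
    subset_size: int
    min_hits: int

    @property
    def rmip(self) -> pd.Series:
        return self.counts / max(self.n_runs, 1)


def resample_rmip(
    phenos: np.ndarray | pd.Series,
    g: GenotypeMatrix,
    engine=association_engine_lm,
    n_runs: int = 100,
    keep_frac: float = 0.87,
    subset_size: int | None = None,
    per_run_alpha: float | None = None,
    min_hits: int = 10,
    seed: int = 0,
    engine_kwargs: dict | None = None,
) -> RmipResult:
    """Resampling stability of marker associations.

    ``n_runs`` random genotype subsets of ``subset_size`` (default
    ``round(keep_frac * n)``, drawn uniformly without replacement) are
    each scored by the association engine; a marker scores a hit in a
    run when its p-value beats ``per_run_alpha`` (default the Bonferroni
    threshold 0.05 / n_markers).  Markers hitting in at least
    ``min_hits`` runs form the stable set.  A failing engine run is
    recorded and excluded rather than aborting the scan.
    """
    y = np.asarray(phenos, dtype=float)
    n = g.n_genotypes
    if subset_size is None:
        subset_size = int(round(keep_frac * n))
    subset_size = min(max(subset_size, 1), n)
    if per_run_alpha is None:
        per_run_alpha = bonferroni_threshold(0.05, g.n_markers)
    rng = np.random.default_rng(seed)
    counts = np.zeros(g.n_markers, dtype=int)
    failed = 0
    kwargs = engine_kwargs or {}
    for _ in range(n_runs):
        idx = np.sort(rng.choice(n, size=subset_size, replace=False))
        try:
            p = engine(y[idx], g.subset_genotypes(idx), **kwargs)
        except Exception:
            failed += 1
            continue
        counts += np.asarray(p) < per_run_alpha
    if failed:
        warnings.warn(f"{failed} resampling run(s) failed; RMIP computed over the rest")
    series = pd.Series(counts, index=g.marker_ids, name="hits")
    stable = series.index[series >= min_hits].tolist()
    return RmipResult(
        counts=series,
        n_runs=n_runs - failed,
        n_failed=failed,
        stable_markers=stable,
        per_run_alpha=per_run_alpha,
        subset_size=subset_size,
        min_hits=min_hits,
    )


# ----------------------------------------------------------------------
# IO
# ----------------------------------------------------------------------
def read_geno_tsv(path: str | Path) -> GenotypeMatrix:
    """Tab-delimited dosage matrix: columns marker, chrom, pos, then one
    0/1/2/NA column per genotype."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    geno_cols = [c for c in df.columns if c not in ("marker", "chrom", "pos")]
    return GenotypeMatrix(
        calls=df[geno_cols].to_numpy(dtype=float),
        marker_ids=df["marker"].tolist(),
        genotype_ids=geno_cols,
        chrom=df["chrom"].tolist() if "chrom" in df else None,
        pos=df["pos"].to_numpy() if "pos" in df else None,
    )


def write_geno_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.calls, columns=g.genotype_ids)
    df.insert(0, "pos", g.pos if g.pos is not None else np.arange(g.n_markers))
    df.insert(0, "chrom", g.chrom if g.chrom is not None else ["1"] * g.n_markers)
    df.insert(0, "marker", g.marker_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (GT field; half-calls and missing
    genotypes become NaN)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    genotype_ids = list(vcf.samples)
    marker_ids, chrom, pos, rows = [], [], [], []
    for var in vcf:
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        row = []
        for gt in var.genotypes:
            a, b = gt[0], gt[1]
            row.append(np.nan if (a < 0 or b < 0) else float((a > 0) + (b > 0)))
        rows.append(row)
    return GenotypeMatrix(
        calls=np.asarray(rows, dtype=float).reshape(len(marker_ids), len(genotype_ids)),
        marker_ids=marker_ids,
        genotype_ids=genotype_ids,
        chrom=chrom,
        pos=np.asarray(pos),
    )


# ----------------------------------------------------------------------
# simulation (study-condition generators for the genetics stage)
# ----------------------------------------------------------------------
def simulate_replicated_phenotypes(
    n_genotypes: int = 100,
    reps: int = 4,
    sigma2_G: float = 1.0,
    sigma2_e: float = 2.0,
    mean: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced one-way random-effects phenotypes: per genotype a random
    effect ~ N(0, sigma2_G) plus per-replicate residuals ~ N(0, sigma2_e),
    around a mean angle typical of sorghum leaves."""
    rng = np.random.default_rng(seed)
    geff = rng.normal(0.0, np.sqrt(sigma2_G), n_genotypes)
    rows = []
    for i in range(n_genotypes):
        for r in range(reps):
            rows.append(
                {
                    "plant_id": f"g{i}_r{r}",
                    "genotype_id": f"g{i}",
                    "timepoint": 0,
                    "leaf_index": 1,
                    "angle_deg": mean + geff[i] + rng.normal(0.0, np.sqrt(sigma2_e)),
                }
            )
    return pd.DataFrame(rows)


def simulate_genotype_matrix(
    n_markers: int = 500,
    n_genotypes: int = 200,
    maf_range: tuple[float, float] = (0.1, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Biallelic markers in Hardy-Weinberg proportions for an inbred-ish
    panel: dosage 0/2 with frequency from ``maf_range`` plus a small
    heterozygote residue (1%)."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(*maf_range, size=n_markers)
    u = rng.random((n_markers, n_genotypes))
    calls = np.where(u < f[:, None] * 0.99, 2.0, np.where(u < f[:, None], 1.0, 0.0))
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan
    return GenotypeMatrix(
        calls=calls,
        marker_ids=[f"m{i}" for i in range(n_markers)],
        genotype_ids=[f"g{j}" for j in range(n_genotypes)],
        chrom=["1"] * n_markers,
        pos=np.arange(1, n_markers + 1) * 1000,
    )


def simulate_gwas_population(
    n_genotypes: int = 200,
    n_markers: int = 500,
    planted_marker: int = 0,
    planted_var_frac: float = 0.15,
    h2: float = 0.6,
    reps: int = 2,
    mean: float = 40.0,
    seed: int = 0,
) -> tuple[pd.Series, GenotypeMatrix, pd.DataFrame]:
    """A mapping population with one planted additive QTL.

    The planted marker explains ``planted_var_frac`` of the genetic
    variance hierarchy: genotypic value = marker effect + polygenic
    residual, scaled so the marker explains the requested fraction of
    phenotypic variance and broad-sense heritability of the per-genotype
    mean phenotype is ``h2``.  Returns (per-genotype mean phenotypes,
    genotype matrix, per-plant replicate table).
    """
    rng = np.random.default_rng(seed)
    g = simulate_genotype_matrix(n_markers=n_markers, n_genotypes=n_genotypes, seed=rng.integers(2**31))
    dosage = g.calls[planted_marker]
    x = (dosage - dosage.mean()) / max(dosage.std(), 1e-9)
    # variance budget (per-genotype phenotype scale = 1)
    var_marker = planted_var_frac
    var_poly = max(h2 - planted_var_frac, 0.0)
    var_env = max(1.0 - h2, 1e-9)
    gv = x * np.sqrt(var_marker) + rng.normal(0, np.sqrt(var_poly), n_genotypes)
    rows = []
    for j in range(n_genotypes):
        for r in range(reps):
            rows.append(
                {
                    "plant_id": f"g{j}_r{r}",
                    "genotype_id": g.genotype_ids[j],
                    "timepoint": 0,
                    "leaf_index": 1,
                    "angle_deg": float(
                        np.clip(mean + 10.0 * (gv[j] + rng.normal(0, np.sqrt(var_env * reps))), 0, 180)
                    ),
                }
            )
    table = pd.DataFrame(rows)
    phenos = table.groupby("genotype_id")["angle_deg"].mean().reindex(g.genotype_ids)
    return phenos, g, table
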