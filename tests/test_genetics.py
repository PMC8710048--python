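import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import leafangle3d as la
from leafangle3d import genetics as gen


# ----------------------------------------------------------------------
# aggregation
# ----------------------------------------------------------------------
def make_table(values):
    """values: dict (plant, timepoint, leaf) -> angle."""
    rows = [
        {"plant_id": p, "genotype_id": f"G_{p}", "timepoint": t, "leaf_index": l, "angle_deg": v}
        for (p, t, l), v in values.items()
    ]
    return pd.DataFrame(rows)


def test_aggregate_constant_table():
    vals = {("p1", t, l): 40.0 for t in range(3) for l in range(1, 5)}
    out = gen.aggregate_angles(make_table(vals), leaves=[1, 2, 3, 4])
    assert out.loc["p1", "angle_deg"] == 40.0
    assert out.loc["p1", "n_cells"] == 12


def test_aggregate_median_of_leaf_medians():
    # leaf medians 30, 40, 50, 60 -> median 45
    vals = {}
    for l, m in zip(range(1, 5), (30, 40, 50, 60)):
        for t, off in zip(range(3), (-5, 0, 5)):
            vals[("p1", t, l)] = m + off
    out = gen.aggregate_angles(make_table(vals), leaves=[1, 2, 3, 4])
    assert out.loc["p1", "angle_deg"] == 45.0


def test_aggregate_single_cell_identity():
    out = gen.aggregate_angles(make_table({("p1", 0, 1): 33.0}), leaves=[1], timepoints=[0])
    assert out.loc["p1", "angle_deg"] == 33.0


def test_aggregate_rejects_empty_selection():
    with pytest.raises(ValueError, match="no data"):
        gen.aggregate_angles(make_table({("p1", 0, 1): 33.0}), leaves=[9])


def test_validate_phenotypes_catches_bad_rows():
    df = make_table({("p1", 0, 1): 33.0})
    gen.validate_phenotypes(df)
    bad = df.copy()
    bad.loc[0, "angle_deg"] = 200.0
    with pytest.raises(ValueError, match="outside"):
        gen.validate_phenotypes(bad)
    dup = pd.concat([df, df])
    with pytest.raises(ValueError, match="duplicate"):
        gen.validate_phenotypes(dup)


# ----------------------------------------------------------------------
# heritability
# ----------------------------------------------------------------------
def test_h2_is_one_without_residual_variance():
    tab = gen.simulate_replicated_phenotypes(20, 3, sigma2_G=2.0, sigma2_e=0.0, seed=1)
    h, vc = la.heritability(tab)
    assert h == pytest.approx(1.0, abs=1e-6)


def test_h2_near_zero_without_genetic_variance():
    tab = gen.simulate_replicated_phenotypes(200, 4, sigma2_G=0.0, sigma2_e=1.0, seed=2)
    h, vc = la.heritability(tab)
    assert h < 0.15


def test_h2_balanced_simulation_recovers_half():
    """s2G=1, s2e=2 with the printed divisor-2 estimator gives
    H2 = 1/(1 + 2/2) = 0.5."""
    h2s = []
    for s in range(40):
        tab = gen.simulate_replicated_phenotypes(100, 4, 1.0, 2.0, seed=s)
        h, _ = la.heritability(tab)
        h2s.append(h)
    assert np.mean(h2s) == pytest.approx(0.5, abs=0.05)


def test_h2_monotone_in_genetic_variance():
    h2s = []
    for s2g in (0.25, 1.0, 4.0):
        vals = []
        for s in range(10):
            tab = gen.simulate_replicated_phenotypes(80, 4, s2g, 2.0, seed=100 + s)
            vals.append(la.heritability(tab)[0])
        h2s.append(np.mean(vals))
    assert h2s[0] < h2s[1] < h2s[2]


def test_h2_requires_replication():
    tab = gen.simulate_replicated_phenotypes(20, 1, 1.0, 1.0, seed=3)
    with pytest.raises(ValueError, match="replicates"):
        la.heritability(tab)


# ----------------------------------------------------------------------
# BLUP screen
# ----------------------------------------------------------------------
def reml_oracle(y, groups):
    """Brute-force REML of the one-way random model: numerically
    maximize the restricted likelihood over (s2g, s2e), then return
    variance components, the GLS mean and mixed-model BLUPs."""
    y = np.asarray(y, dtype=float)
    labels, ginv = np.unique(groups, return_inverse=True)
    k = len(labels)
    z = np.zeros((len(y), k))
    z[np.arange(len(y)), ginv] = 1.0
    x = np.ones((len(y), 1))

    def neg_restricted_ll(log_s):
        s2g, s2e = np.exp(log_s)
        v = s2g * (z @ z.T) + s2e * np.eye(len(y))
        vi = np.linalg.inv(v)
        xvx = x.T @ vi @ x
        beta = np.linalg.solve(xvx, x.T @ vi @ y)
        r = y - x @ beta
        _, ld_v = np.linalg.slogdet(v)
        _, ld_x = np.linalg.slogdet(xvx)
        return 0.5 * (ld_v + ld_x + r @ vi @ r)

    res = optimize.minimize(neg_restricted_ll, np.log([1.0, 1.0]), method="Nelder-Mead")
    s2g, s2e = np.exp(res.x)
    v = s2g * (z @ z.T) + s2e * np.eye(len(y))
    vi = np.linalg.inv(v)
    beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y).item()
    blup = s2g * z.T @ vi @ (y - beta)
    return s2g, s2e, beta, pd.Series(blup, index=labels)


def test_blup_matches_brute_force_reml_oracle():
    rng = np.random.default_rng(5)
    rows = []
    for i, n_i in enumerate((2, 3, 2, 4, 3)):
        eff = rng.normal(0, 2.0)
        for r in range(n_i):
            rows.append(
                {"plant_id": f"g{i}r{r}", "genotype_id": f"g{i}", "timepoint": 0,
                 "leaf_index": 1, "angle_deg": 40 + eff + rng.normal(0, 1.0)}
            )
    tab = pd.DataFrame(rows)
    res = la.blup_outlier_screen(tab)
    s2g, s2e, beta, blup = reml_oracle(tab["angle_deg"], tab["genotype_id"])
    assert res.components.sigma2_G == pytest.approx(s2g, rel=0.02, abs=1e-3)
    assert res.components.sigma2_e == pytest.approx(s2e, rel=0.02, abs=1e-3)
    for g in blup.index:
        assert res.blups[g] == pytest.approx(blup[g], rel=0.02, abs=0.02)


def test_blups_shrink_toward_zero():
    tab = gen.simulate_replicated_phenotypes(50, 3, 1.0, 2.0, seed=6)
    res = la.blup_outlier_screen(tab)
    means = tab.groupby("genotype_id")["angle_deg"].mean() - res.components.grand_mean
    for g in res.blups.index:
        assert abs(res.blups[g]) <= abs(means[g]) + 1e-9


def test_no_outliers_removed_in_clean_data():
    tab = gen.simulate_replicated_phenotypes(50, 4, 1.0, 1.0, seed=7)
    res = la.blup_outlier_screen(tab)
    assert res.removed == []
    assert len(res.kept) == len(tab)


def test_planted_extreme_genotype_removed():
    tab = gen.simulate_replicated_phenotypes(80, 4, 1.0, 1.0, seed=8)
    bad = tab["genotype_id"] == "g0"
    tab.loc[bad, "angle_deg"] += 60.0  # way beyond 5 SD of the BLUP spread
    res = la.blup_outlier_screen(tab)
    assert res.removed == ["g0"]
    assert "g0" not in set(res.kept["genotype_id"])


# ----------------------------------------------------------------------
# marker QC + thresholds
# ----------------------------------------------------------------------
def toy_matrix():
    calls = np.array(
        [
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # monomorphic -> low-maf
            [0, 2, 0, 2, 0, 2, 0, 2, 0, 2],  # maf 0.5, het 0 -> kept
            [1, 1, 0, 2, 0, 2, 0, 2, 0, 2],  # het 0.2 -> high-het
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 2],  # maf 0.1, het 0 -> kept
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 1],  # maf 0.05, het 0.1 -> high-het
            [2, 2, 2, 2, 2, 2, 2, 2, 2, 0],  # maf 0.1 (alt major) -> kept
            [np.nan] * 10,  # all missing
            [0, 0, 0, 0, 0, 0, 0, 0, np.nan, 2],  # maf 1/9 -> kept
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # monomorphic
            [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # maf 0.05, het 0.1 -> high-het
        ]
    )
    return gen.GenotypeMatrix(
        calls=calls,
        marker_ids=[f"m{i}" for i in range(10)],
        genotype_ids=[f"g{j}" for j in range(10)],
    )


def test_filter_markers_matches_hand_tally():
    g = toy_matrix()
    kept, log = gen.filter_markers(g)
    assert kept.marker_ids == ["m1", "m3", "m5", "m7"]
    assert log.loc[log["marker"] == "m0", "reason"].item() == "low-maf"
    assert log.loc[log["marker"] == "m2", "reason"].item() == "high-het"
    assert log.loc[log["marker"] == "m6", "reason"].item() == "all-missing"


def test_filter_markers_idempotent():
    kept, _ = gen.filter_markers(toy_matrix())
    again, _ = gen.filter_markers(kept)
    assert again.marker_ids == kept.marker_ids
    assert np.array_equal(again.calls, kept.calls, equal_nan=True)


def test_maf_and_het_ranges():
    g = toy_matrix()
    maf = g.maf()
    het = g.het()
    ok = ~np.isnan(maf)
    assert ((maf[ok] >= 0) & (maf[ok] <= 0.5)).all()
    assert ((het[ok] >= 0) & (het[ok] <= 1)).all()


def test_bonferroni_threshold_basics():
    assert gen.bonferroni_threshold(0.05, 1) == 0.05
    assert gen.bonferroni_threshold(0.05, 100) == pytest.approx(5e-4)
    with pytest.raises(ValueError):
        gen.bonferroni_threshold(0.05, 0)
    with pytest.raises(ValueError):
        gen.bonferroni_threshold(1.5, 10)


# ----------------------------------------------------------------------
# association engine
# ----------------------------------------------------------------------
def test_engine_null_pvalues_uniform():
    g = gen.simulate_genotype_matrix(n_markers=2000, n_genotypes=200, seed=9)
    y = np.random.default_rng(9).normal(size=200)
    p = la.association_engine_lm(y, g)
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_engine_detects_planted_marker():
    """A marker explaining 20% of phenotypic variance at n=200 is found
    at p < 1e-5 in nearly every replicate."""
    rng = np.random.default_rng(10)
    found = 0
    n_rep = 60
    for _ in range(n_rep):
        g = gen.simulate_genotype_matrix(n_markers=20, n_genotypes=200,
                                         seed=int(rng.integers(2**31)))
        x = g.calls[0]
        xs = (x - x.mean()) / x.std()
        y = np.sqrt(0.2) * xs + np.sqrt(0.8) * rng.normal(size=200)
        p = la.association_engine_lm(y, g)
        found += p[0] < 1e-5
    assert found >= 0.95 * n_rep


def test_engine_constant_marker_gets_p_one():
    g = toy_matrix()
    y = np.random.default_rng(0).normal(size=10)
    p = la.association_engine_lm(y, g)
    assert p[0] == 1.0  # monomorphic marker
    assert np.isfinite(p).all()


def test_engine_with_pcs_remains_calibrated():
    """On a structure-free simulation, PC covariates leave null p-values
    calibrated and a planted signal detectable."""
    rng = np.random.default_rng(11)
    g = gen.simulate_genotype_matrix(n_markers=500, n_genotypes=200, seed=11)
    x = g.calls[0]
    y = np.sqrt(0.2) * (x - x.mean()) / x.std() + np.sqrt(0.8) * rng.normal(size=200)
    p0 = la.association_engine_lm(y, g, n_pcs=0)
    p3 = la.association_engine_lm(y, g, n_pcs=3)
    assert p3[0] < 1e-5 and p0[0] < 1e-5
    assert stats.kstest(p3[1:], "uniform").pvalue > 0.01


def test_engine_handles_missing_calls():
    g = gen.simulate_genotype_matrix(n_markers=50, n_genotypes=100, missing_rate=0.1, seed=12)
    y = np.random.default_rng(12).normal(size=100)
    p = la.association_engine_lm(y, g)
    assert np.isfinite(p).all()


# ----------------------------------------------------------------------
# RMIP
# ----------------------------------------------------------------------
def test_rmip_counts_match_brute_force_tally():
    """With a deterministic fake engine the hit counts equal a
    hand-computed tally of the per-run p matrix."""
    rng = np.random.default_rng(13)
    g = gen.simulate_genotype_matrix(n_markers=5, n_genotypes=30, seed=13)
    pmat = rng.random((20, 5))  # p-values per (run, marker)
    calls = {"i": 0}

    def fake_engine(y, gsub):
        p = pmat[calls["i"] % 20]
        calls["i"] += 1
        return p

    res = la.resample_rmip(
        np.zeros(30), g, engine=fake_engine, n_runs=20, per_run_alpha=0.3, min_hits=5, seed=1
    )
    expect = (pmat < 0.3).sum(axis=0)
    assert list(res.counts) == list(expect)
    assert res.stable_markers == [g.marker_ids[i] for i in range(5) if expect[i] >= 5]


def test_rmip_threshold_is_inclusive_at_min_hits():
    g = gen.simulate_genotype_matrix(n_markers=2, n_genotypes=30, seed=14)
    seq = iter([np.array([0.0, 1.0])] * 10 + [np.array([1.0, 1.0])] * 90)

    def fake_engine(y, gsub):
        return next(seq)

    res = la.resample_rmip(np.zeros(30), g, engine=fake_engine, n_runs=100,
                           per_run_alpha=0.5, min_hits=10, seed=2)
    assert res.counts.iloc[0] == 10
    assert res.stable_markers == ["m0"]  # exactly 10 of 100 counts as stable
    assert res.counts.iloc[1] == 0


def test_rmip_single_full_run_reduces_to_thresholded_scan():
    phen, g, _ = gen.simulate_gwas_population(seed=15)
    res = la.resample_rmip(phen.to_numpy(), g, n_runs=1, keep_frac=1.0, min_hits=1, seed=3)
    p = la.association_engine_lm(phen.to_numpy(), g)
    scan = [m for m, hit in zip(g.marker_ids, p < res.per_run_alpha) if hit]
    assert res.stable_markers == scan


def test_rmip_survives_engine_failures():
    g = gen.simulate_genotype_matrix(n_markers=3, n_genotypes=30, seed=16)
    calls = {"i": 0}

    def flaky(y, gsub):
        calls["i"] += 1
        if calls["i"] % 2:
            raise RuntimeError("boom")
        return np.array([0.0, 1.0, 1.0])

    with pytest.warns(UserWarning, match="failed"):
        res = la.resample_rmip(np.zeros(30), g, engine=flaky, n_runs=10,
                               per_run_alpha=0.5, min_hits=1, seed=4)
    assert res.n_runs == 5
    assert res.n_failed == 5
    assert res.counts.iloc[0] == 5


# ----------------------------------------------------------------------
# IO
# ----------------------------------------------------------------------
def test_geno_tsv_roundtrip(tmp_path):
    g = gen.simulate_genotype_matrix(n_markers=20, n_genotypes=8, missing_rate=0.1, seed=17)
    f = tmp_path / "geno.tsv"
    gen.write_geno_tsv(g, f)
    back = gen.read_geno_tsv(f)
    assert back.marker_ids == g.marker_ids
    assert back.genotype_ids == g.genotype_ids
    assert np.array_equal(back.calls, g.calls, equal_nan=True)


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tg1\tg2\tg3\tg4
1\t100\tsnp1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t./.
1\t200\tsnp2\tG\tC\t.\t.\t.\tGT\t1/1\t1/1\t0/0\t0/.
1\t300\t.\tC\tA\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0
"""


def test_vcf_reader_dosages_and_half_calls(tmp_path):
    f = tmp_path / "toy.vcf"
    f.write_text(VCF_TEXT)
    g = gen.read_vcf(f)
    assert g.genotype_ids == ["g1", "g2", "g3", "g4"]
    assert g.marker_ids[:2] == ["snp1", "snp2"]
    assert g.marker_ids[2] == "1_300"
    row = g.calls[0]
    assert row[0] == 0 and row[1] == 1 and row[2] == 2 and np.isnan(row[3])
    assert np.isnan(g.calls[1][3])  # half-call -> missing
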