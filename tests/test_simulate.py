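"""Generator contract: interpolation endpoints, UPR bump geometry,
negative-binomial moments, and seeded determinism."""
import numpy as np
import pytest

from islet_identity import (GenePanel, PopulationConfig, expected_profile,
                            expected_profiles, simulate_counts)
from islet_identity.errors import EmptyResultError, FormatError


def test_endpoints_match_state_means(panel):
    """At t=0 signature genes sit at their beta-state means; at t=1 at
    their alpha-state means (fold-reduced where not at home)."""
    mu0 = expected_profile(panel, 0.0)
    mu1 = expected_profile(panel, 1.0)
    bi = panel.index_of(panel.beta_genes)
    ai = panel.index_of(panel.alpha_genes)
    f = panel.signature_fold
    np.testing.assert_allclose(mu0[bi], panel.base_mean[bi], rtol=1e-12)
    np.testing.assert_allclose(mu1[bi], panel.base_mean[bi] / f, rtol=1e-12)
    np.testing.assert_allclose(mu0[ai], panel.base_mean[ai] / f, rtol=1e-12)
    np.testing.assert_allclose(mu1[ai], panel.base_mean[ai], rtol=1e-12)
    hk = panel.index_of(panel.housekeeping_genes)
    np.testing.assert_allclose(mu0[hk], panel.base_mean[hk], rtol=1e-12)
    np.testing.assert_allclose(mu1[hk], panel.base_mean[hk], rtol=1e-12)


def test_bump_peak_ratio_is_amplitude(panel):
    """An IRE1a gene with amplitude log(3) is exactly 3x its baseline at
    the bump center (the bump vanishes identically far from the center)."""
    gi = panel.index_of(["XBP1"])[0]
    c = panel.gene_center("XBP1")
    at_peak = expected_profile(panel, c)[gi]
    at_zero = expected_profile(panel, 0.0)[gi]
    assert at_zero == pytest.approx(panel.base_mean[gi], abs=1e-9)
    assert at_peak / at_zero == pytest.approx(3.0, abs=1e-9)


def test_signature_monotone_in_t(panel):
    """Beta-signature means never increase with t; alpha never decrease."""
    ts = np.linspace(0, 1, 41)
    mu = expected_profiles(panel, ts)
    bi = panel.index_of(panel.beta_genes)
    ai = panel.index_of(panel.alpha_genes)
    assert (np.diff(mu[bi], axis=1) <= 1e-12).all()
    assert (np.diff(mu[ai], axis=1) >= -1e-12).all()


def test_atf6_ramp_down_wfs1_up(panel):
    atf6 = panel.index_of(["ATF6"])[0]
    wfs1 = panel.index_of(["WFS1"])[0]
    mu = expected_profiles(panel, np.linspace(0, 1, 11))
    assert (np.diff(mu[atf6]) < 0).all()
    assert (np.diff(mu[wfs1]) > 0).all()
    assert mu[atf6, -1] == pytest.approx(
        panel.base_mean[atf6] * panel.atf6_floor)


@pytest.mark.parametrize("bad_t", [-0.01, 1.01, 2.0])
def test_t_out_of_domain(panel, bad_t):
    with pytest.raises(ValueError):
        expected_profile(panel, bad_t)


def test_seeded_determinism(small_panel):
    cfg = PopulationConfig(n_beta=30, n_alpha=30, n_traced=40, seed=13)
    cm1, tr1 = simulate_counts(small_panel, cfg)
    cm2, tr2 = simulate_counts(small_panel, cfg)
    assert (cm1.counts != cm2.counts).nnz == 0
    assert tr1.equals(tr2)
    assert cm1.cell_ids == cm2.cell_ids


def test_no_traced_rows_when_n_traced_zero(small_panel):
    cfg = PopulationConfig(n_beta=10, n_alpha=10, n_traced=0, seed=0)
    cm, truth = simulate_counts(small_panel, cfg)
    assert (truth["true_type"] == "traced").sum() == 0
    assert cm.shape == (small_panel.n_genes, 20)


def test_zero_cells_errors(small_panel):
    with pytest.raises(EmptyResultError):
        simulate_counts(small_panel, PopulationConfig(
            n_beta=0, n_alpha=0, n_traced=0))


def test_counts_shape_and_integrality(default_run, small_panel):
    cm = default_run["counts"]
    assert cm.shape == (small_panel.n_genes,
                        len(default_run["truth"]))
    assert cm.counts.data.dtype == np.int64
    assert cm.counts.data.min() >= 0


def test_truth_invariants(default_run):
    truth = default_run["truth"]
    assert truth["cell_id"].is_unique
    assert truth["t"].between(0, 1).all()
    assert (truth["library_factor"] > 0).all()
    assert set(truth["true_type"]) == {"beta", "alpha", "traced"}


def test_poisson_limit_mean_recovery(small_panel):
    """With dispersion ~inf (1e6) and unit library factors, the empirical
    per-gene mean over 10,000 beta-endpoint cells matches the expected
    profile at t=0 within 3 standard errors."""
    near_poisson = GenePanel(
        **{**_panel_kwargs(small_panel),
           "dispersion": np.full(small_panel.n_genes, 1e6)})
    cfg = PopulationConfig(n_beta=10_000, n_alpha=0, n_traced=0,
                           endpoint_jitter=1e-9,
                           library_size_log_sd=0.0, seed=5)
    cm, _ = simulate_counts(near_poisson, cfg)
    emp_mean = np.asarray(cm.counts.mean(axis=1)).ravel()
    emp_sd = np.sqrt(np.maximum(_row_var(cm.counts), 1e-12))
    expected = expected_profile(near_poisson, 0.0)
    se = emp_sd / np.sqrt(10_000)
    assert (np.abs(emp_mean - expected) <= 3 * np.maximum(se, 1e-6)).all()


def test_overdispersion_exceeds_mean(small_panel):
    """Finite dispersion: empirical variance > mean for abundant genes
    at fixed t (10,000 draws)."""
    cfg = PopulationConfig(n_beta=10_000, n_alpha=0, n_traced=0,
                           endpoint_jitter=1e-9,
                           library_size_log_sd=0.0, seed=6)
    cm, _ = simulate_counts(small_panel, cfg)
    gi = small_panel.index_of(["INS", "ACTB", "GAPDH"])
    var = _row_var(cm.counts)[gi]
    mean = np.asarray(cm.counts.mean(axis=1)).ravel()[gi]
    assert (var > mean).all()


def test_panel_validation_rejects_bad_inputs(small_panel):
    kwargs = _panel_kwargs(small_panel)
    with pytest.raises(FormatError):
        GenePanel(**{**kwargs,
                     "base_mean": np.zeros(small_panel.n_genes)})
    with pytest.raises(FormatError):
        GenePanel(**{**kwargs, "alpha_genes": kwargs["beta_genes"]})


def test_mixture_weights_validated():
    with pytest.raises(FormatError):
        PopulationConfig(traced_mixture=(0.5, 0.5, 0.5))
    with pytest.raises(FormatError):
        PopulationConfig(n_beta=-1)


def _panel_kwargs(p: GenePanel) -> dict:
    return dict(gene_ids=p.gene_ids, beta_genes=p.beta_genes,
                alpha_genes=p.alpha_genes, ire1a_genes=p.ire1a_genes,
                perk_genes=p.perk_genes, atf6_genes=p.atf6_genes,
                housekeeping_genes=p.housekeeping_genes,
                base_mean=p.base_mean, dispersion=p.dispersion,
                bump_center=dict(p.bump_center))


def _row_var(m):
    dense = np.asarray(m.todense(), dtype=float)
    return dense.var(axis=1, ddof=1)
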