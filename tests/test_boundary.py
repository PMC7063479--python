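"""Surrogate boundary, critical concentrations, stratification, LOO."""

import warnings

import numpy as np
import pytest

from cardiorisk.boundary import (
    ANCHOR_MULTIPLES,
    GPBoundary,
    critical_concentration,
    loo_validate,
    stratify,
    surrogate_boundary,
)
from cardiorisk.drugs import DrugRecord, block_pair, drug_by_name
from cardiorisk.gp import active_learning_loop


def test_surrogate_region_features(surrogate):
    # beyond 60% I_CaL block the heart stays safe at any I_Kr block
    assert surrogate.region((0.7, 0.99)) is False
    # the pure-I_Kr wall sits at the chlorpromazine anchor ordinate
    assert surrogate.region((0.0, 0.684 + 0.01)) is True
    assert surrogate.region((0.0, 0.684 - 0.01)) is False


def test_surrogate_passes_through_all_anchors(surrogate, drugs):
    for name, mult in ANCHOR_MULTIPLES.items():
        bp = block_pair(drug_by_name(drugs, name), mult)
        assert surrogate.region((bp.cal_block, bp.kr_block)) is True
        assert surrogate.region((bp.cal_block, bp.kr_block - 0.005)) is False


def test_surrogate_threshold_monotone_beyond_dip(surrogate):
    xs = np.linspace(0.05, 0.60, 200)
    assert np.all(np.diff(surrogate.threshold(xs)) >= -1e-12)


def test_surrogate_requires_calibration_drugs():
    with pytest.raises(ValueError, match="calibration"):
        surrogate_boundary([DrugRecord("aspirin", 100.0, 100.0, 10.0)])


def test_critical_concentration_examples(surrogate, drugs):
    dof = critical_concentration(drug_by_name(drugs, "dofetilide"), surrogate)
    assert dof.multiple == pytest.approx(9.0, abs=0.1)

    nit = critical_concentration(drug_by_name(drugs, "nitrendipine"), surrogate)
    assert nit.never_crosses

    thi = critical_concentration(drug_by_name(drugs, "thioridazine"), surrogate)
    assert thi.multiple == pytest.approx(0.1, rel=2e-3)
    assert surrogate.region((thi.crossing.cal_block, thi.crossing.kr_block))


def test_critical_concentration_scan_errors(surrogate, drugs):
    d = drug_by_name(drugs, "dofetilide")
    with pytest.raises(ValueError):
        critical_concentration(d, surrogate, scan_lo=-1.0)
    with pytest.raises(ValueError):
        critical_concentration(d, surrogate, scan_lo=10.0, scan_hi=1.0)
    with pytest.raises(ValueError):
        critical_concentration(d, surrogate, n_scan=1)


def dense_scan_oracle(drug, boundary, n=100_000):
    """Independent dense-scan minimum: first arrhythmic multiple on a
    10^5-point log grid, using its own Hill arithmetic."""
    m = np.logspace(-2, 3, n)
    c = m * drug.cmax
    cal = c / (c + drug.ic50_cal) if drug.ic50_cal else np.zeros_like(c)
    kr = c / (c + drug.ic50_kr) if drug.ic50_kr else np.zeros_like(c)
    arr = (cal < boundary.x_wall) & (kr >= np.interp(cal, boundary.xs, boundary.ys))
    idx = np.flatnonzero(arr)
    return m[idx[0]] if idx.size else None


def assert_matches_dense_scan(drug, boundary, rel=2e-3):
    """Package result vs the independent dense-scan minimum.

    The two agree within the scan resolution, except that a calibration
    anchor sitting at a local-minimum vertex of the boundary is an
    isolated tangency the fixed oracle grid cannot contain; such a point
    is accepted only after verifying it really is an isolated arrhythmic
    touch below the oracle's first hit.
    """
    ours = critical_concentration(drug, boundary)
    ref = dense_scan_oracle(drug, boundary)
    if ref is None:
        assert ours.never_crosses, drug.name
        return
    assert not ours.never_crosses, drug.name
    m = ours.multiple
    assert boundary.region((ours.crossing.cal_block, ours.crossing.kr_block)), drug.name
    if m == pytest.approx(ref, rel=rel):
        return
    assert m < ref, drug.name  # never above the oracle minimum
    for probe in (m * (1 - rel), m * (1 + rel)):
        bp = block_pair(drug, probe)
        assert not boundary.region((bp.cal_block, bp.kr_block)), drug.name


def test_critical_concentration_matches_dense_scan_all_drugs(surrogate, drugs):
    for d in drugs:
        assert_matches_dense_scan(d, surrogate)


def test_stratify_counts_and_membership(surrogate, drugs):
    rep = stratify(drugs, surrogate)
    counts = rep["category"].value_counts()
    assert counts["high"] == 14 and counts["low"] == 9
    cats = rep.set_index("name")["category"]
    for name in ("chlorpromazine", "cisapride", "tedisamil"):
        assert cats[name] == "high"  # vertical trajectories always cross
    for name in ("nifedipine", "nitrendipine", "diltiazem", "verapamil"):
        assert cats[name] == "low"
    # report sorted by critical multiple, never-crossing drugs last
    mults = rep["critical_multiple"].to_numpy()
    finite = mults[~np.isnan(mults)]
    assert np.all(np.diff(finite) >= 0)
    assert np.all(np.isnan(mults[len(finite):]))


def test_stratify_empty_table(surrogate):
    assert stratify([], surrogate).empty


def test_pure_kr_blocker_is_high_risk(surrogate):
    d = DrugRecord("probe", None, 1.0, 1.0)
    rep = stratify([d], surrogate)
    assert rep.loc[0, "category"] == "high"
    # vertical trajectory crosses B(0)=0.684 at C = 0.684/0.316 nM
    assert rep.loc[0, "critical_multiple"] == pytest.approx(2.16, abs=0.05)


def test_stratify_monotone_in_threshold(surrogate, drugs):
    lo = stratify(drugs, surrogate, threshold=100.0).set_index("name")["category"]
    hi = stratify(drugs, surrogate, threshold=500.0).set_index("name")["category"]
    for name in lo.index:
        assert not (lo[name] == "high" and hi[name] == "low")


def test_gp_learned_boundary_reproduces_stratification(surrogate_learning_runs, surrogate, drugs):
    """Stratifying against boundaries learned from 40 oracle queries
    agrees with the exact-boundary stratification for >= 22 of 23 drugs
    in >= 8 of 10 seeds.

    Full 23/23 agreement is not a robust expectation: bepridil's
    trajectory only grazes the surrogate boundary (its calibration
    anchor is a local-maximum vertex, penetration depth ~1e-3 block
    units), far below what 40 oracle queries can resolve; every
    transversally crossing drug must match.
    """
    exact = stratify(drugs, surrogate).set_index("name")["category"]
    hits = 0
    for run in surrogate_learning_runs:
        cats = stratify(drugs, GPBoundary(run.model)).set_index("name")["category"]
        hits += int((cats.reindex(exact.index) == exact).sum() >= 22)
    assert hits >= 8


def test_loo_separated_features_perfect():
    mult = [1.0, 2.0, 5.0, 8.0, 10.0, None, None, None, None, None]
    labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
    acc, report = loo_validate(mult, labels, seed=0)
    assert acc == 1.0
    assert report["predicted"].notna().all()


def test_loo_permuted_labels_no_better_than_chance():
    """Labels permuted independently of the critical multiples carry no
    signal: mean LOO accuracy stays at or below the chance band.

    It sits visibly *below* 0.5 here — the well-known pessimistic bias
    of leave-one-out on pure label noise, where the training majority
    flips against each held-out label — so the informative bound is the
    upper one (contrast with 1.0 for separated features above).
    """
    rng = np.random.default_rng(77)
    mult = list(rng.uniform(0.1, 300, size=12)) + [None] * 11
    labels = np.array([1] * 12 + [0] * 11)
    accs = []
    for _ in range(20):
        perm = rng.permutation(labels)
        accs.append(loo_validate(mult, perm, seed=0)[0])
    assert np.mean(accs) <= 0.65


def test_loo_outlier_fold_misclassified():
    """A lone low-risk drug with a finite crossing far above the rest is
    misclassified when held out (no similar compound in training)."""
    mult = [0.1, 0.3, 4.4, 4.9, 154.9, 282.6, 400.0] + [None] * 8
    labels = [1, 1, 1, 1, 1, 1, 0] + [0] * 8
    acc, report = loo_validate(mult, labels, seed=0)
    assert report.loc[6, "correct"] == 0.0
    assert acc < 1.0


def test_loo_single_class_fold_skipped():
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        acc, report = loo_validate([1.0, 2.0, None], [1, 1, 0], seed=0)
        assert any("skipped" in str(x.message) for x in w)
    assert np.isnan(report.loc[2, "predicted"]) or report["predicted"].isna().any()


def test_loo_misaligned_inputs_error():
    with pytest.raises(ValueError, match="align"):
        loo_validate([1.0, 2.0], [1])
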