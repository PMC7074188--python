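"""Mutual information, permutation/bootstrap filtering and DPI pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirmaster import (
    NetInfParams,
    TRN,
    apply_dpi,
    bootstrap_filter,
    infer_trn,
    mutual_information,
    permutation_filter,
)
from mirmaster.netinf import _EDGE_COLUMNS, regulator_mi_matrix


def _expr(values, prefix="R"):
    values = np.atleast_2d(np.asarray(values, float))
    return pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
                        columns=[f"S{i}" for i in range(values.shape[1])])


# ---------------------------------------------------------------------------
# mutual_information
# ---------------------------------------------------------------------------

def test_mi_of_constant_is_zero():
    rng = np.random.default_rng(0)
    x = rng.normal(size=100)
    assert mutual_information(x, np.full(100, 3.0), 5) == pytest.approx(0.0, abs=1e-12)


def test_mi_identity_attains_log_nbins():
    x = np.random.default_rng(1).normal(size=1000)
    assert mutual_information(x, x, 10) == pytest.approx(np.log(10), abs=1e-9)


def test_mi_symmetric():
    rng = np.random.default_rng(2)
    for _ in range(10):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert mutual_information(x, y, 5) == mutual_information(y, x, 5)


def test_mi_matches_hand_contingency_table():
    # 12 samples, 2 bins: ranks 1..6 -> bin 0, 7..12 -> bin 1
    x = np.arange(12, dtype=float)
    y = np.array([0, 1, 2, 3, 9, 8, 4, 5, 10, 11, 7, 6], dtype=float)
    # joint table of (x-bin, y-bin): x low: y bins {0,1,2,3,9->1? no}
    # enumerate by hand: x bin = i<6; y bin = rank(y)>=7
    xb = x >= 6
    yb = np.argsort(np.argsort(y)) >= 6
    counts = np.zeros((2, 2))
    for a, b in zip(xb, yb):
        counts[int(a), int(b)] += 1
    n = 12.0
    expected = 0.0
    for a, b in itertools.product(range(2), range(2)):
        pij = counts[a, b] / n
        if pij > 0:
            expected += pij * np.log(pij / (counts[a].sum() / n * counts[:, b].sum() / n))
    assert mutual_information(x, y, 2) == pytest.approx(expected, abs=1e-12)


def test_mi_input_validation():
    with pytest.raises(ValueError):
        mutual_information(np.arange(4), np.arange(4), 2)   # too short
    with pytest.raises(ValueError):
        mutual_information(np.arange(10), np.arange(10), 1)  # too few bins


# ---------------------------------------------------------------------------
# permutation_filter
# ---------------------------------------------------------------------------

def test_permutation_filter_deterministic():
    rng = np.random.default_rng(3)
    reg = _expr(rng.normal(size=(3, 60)), "R")
    tgt = _expr(rng.normal(size=(5, 60)), "G")
    a = permutation_filter(reg, tgt, n_perm=100, alpha=0.5, seed=9)
    b = permutation_filter(reg, tgt, n_perm=100, alpha=0.5, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_perfect_dependence_hits_minimal_p():
    rng = np.random.default_rng(4)
    x = rng.normal(size=200)
    reg = _expr(x, "R")
    tgt = _expr(np.vstack([x, rng.normal(size=(4, 200))]), "G")
    edges = permutation_filter(reg, tgt, n_perm=100, alpha=0.05, seed=1)
    assert ("R0", "G0") in set(zip(edges.regulator, edges.target))
    row = edges[(edges.regulator == "R0") & (edges.target == "G0")].iloc[0]
    assert row.perm_p == pytest.approx(1.0 / 101.0)


def test_mismatched_sample_axes_rejected():
    reg = _expr(np.zeros((1, 10)))
    tgt = _expr(np.zeros((1, 12)), "G")
    with pytest.raises(ValueError, match="sample axis"):
        permutation_filter(reg, tgt, n_perm=100)


def test_permutation_null_retention_below_alpha():
    """On independent data the BH-controlled retention stays near zero,
    well under alpha + 0.02 (averaged over seeds)."""
    fracs = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        reg = _expr(rng.normal(size=(20, 50)), "R")
        tgt = _expr(rng.normal(size=(30, 50)), "G")
        edges = permutation_filter(reg, tgt, n_perm=100, alpha=0.05, seed=seed)
        fracs.append(len(edges) / (20 * 30))
    assert np.mean(fracs) <= 0.05 + 0.02


# ---------------------------------------------------------------------------
# bootstrap_filter
# ---------------------------------------------------------------------------

def test_bootstrap_requires_min_resamples():
    with pytest.raises(ValueError, match="n_boot"):
        bootstrap_filter(pd.DataFrame(columns=_EDGE_COLUMNS), _expr(np.zeros((1, 10))),
                         _expr(np.zeros((1, 10)), "G"), n_boot=5)


def test_bootstrap_zero_consensus_is_noop():
    rng = np.random.default_rng(5)
    reg = _expr(rng.normal(size=(2, 80)), "R")
    tgt = _expr(rng.normal(size=(6, 80)), "G")
    edges = permutation_filter(reg, tgt, n_perm=100, alpha=1.1, seed=2)
    out = bootstrap_filter(edges, reg, tgt, n_boot=10, consensus=0.0, seed=2)
    assert set(zip(out.regulator, out.target)) == set(zip(edges.regulator, edges.target))


def test_bootstrap_keeps_strong_edge_drops_noise():
    rng = np.random.default_rng(6)
    n = 200
    x = rng.normal(size=n)
    reg = _expr(x, "R")
    strong = -2.0 * x + rng.normal(0, 0.25, n)
    noise = rng.normal(size=(5, n))
    tgt = _expr(np.vstack([strong, noise]), "G")
    edges = permutation_filter(reg, tgt, n_perm=200, alpha=1.1, seed=3)
    out = bootstrap_filter(edges, reg, tgt, n_boot=50, consensus=0.95, seed=3)
    kept = set(zip(out.regulator, out.target))
    assert ("R0", "G0") in kept
    support = dict(zip(zip(out.regulator, out.target), out.boot_support))
    assert support[("R0", "G0")] == 1.0
    # pure-noise pairs: support far below consensus
    all_support = dict(zip(zip(edges.regulator, edges.target),
                           bootstrap_filter(edges, reg, tgt, n_boot=50, consensus=0.0,
                                            seed=3).boot_support))
    noise_support = [v for k, v in all_support.items() if k != ("R0", "G0")]
    assert max(noise_support) < 0.95


# ---------------------------------------------------------------------------
# DPI
# ---------------------------------------------------------------------------

def _trn_from(edges: dict, rr: dict) -> TRN:
    regs = sorted({r for r, _ in edges} | {a for a, _ in rr} | {b for _, b in rr})
    rows = [
        {"regulator": r, "target": t, "mi": mi, "perm_p": 0.01, "perm_p_fit": 0.001,
         "adj_perm_p": 0.01, "boot_support": 1.0}
        for (r, t), mi in sorted(edges.items())
    ]
    mat = pd.DataFrame(0.0, index=regs, columns=regs)
    for (a, b), mi in rr.items():
        mat.loc[a, b] = mi
        mat.loc[b, a] = mi
    return TRN(edges=pd.DataFrame(rows, columns=_EDGE_COLUMNS), reg_reg_mi=mat)


def test_dpi_single_triplet_removes_weakest():
    trn = _trn_from({("m1", "g"): 0.9, ("m2", "g"): 0.3}, {("m1", "m2"): 0.8})
    out = apply_dpi(trn, eps=0.0)
    assert set(zip(out.edges.regulator, out.edges.target)) == {("m1", "g")}


def test_dpi_spares_edges_when_regulator_pair_is_weakest():
    trn = _trn_from({("m1", "g"): 0.9, ("m2", "g"): 0.3}, {("m1", "m2"): 0.1})
    out = apply_dpi(trn, eps=0.0)
    assert len(out.edges) == 2


def test_dpi_tie_removes_nothing():
    trn = _trn_from({("m1", "g"): 0.3, ("m2", "g"): 0.3}, {("m1", "m2"): 0.8})
    out = apply_dpi(trn, eps=0.0)
    assert len(out.edges) == 2


def test_dpi_missing_reg_reg_entry_raises():
    trn = _trn_from({("m1", "g"): 0.9, ("m2", "g"): 0.3}, {("m1", "m2"): 0.8})
    trn.reg_reg_mi = trn.reg_reg_mi.drop(index="m2", columns="m2")
    with pytest.raises(ValueError, match="regulator-regulator"):
        apply_dpi(trn)


def _brute_force_dpi(edges: dict, rr: dict, eps: float) -> set:
    """Independent re-statement of the pruning rule by full triplet enumeration."""
    regs = sorted({r for r, _ in edges})
    marked = set()
    for r1, r2 in itertools.combinations(regs, 2):
        shared = {t for r, t in edges if r == r1} & {t for r, t in edges if r == r2}
        for g in shared:
            vals = {
                (r1, g): edges[(r1, g)],
                (r2, g): edges[(r2, g)],
                "rr": rr[tuple(sorted((r1, r2)))],
            }
            items = sorted(vals.items(), key=lambda kv: kv[1])
            weakest, second, third = items[0], items[1], items[2]
            strictly_min = (
                weakest[1] < (1 - eps) * second[1] and weakest[1] < (1 - eps) * third[1]
            )
            if strictly_min and weakest[0] != "rr":
                marked.add(weakest[0])
    return set(edges) - marked


@pytest.mark.parametrize("eps", [0.0, 0.1])
def test_dpi_matches_brute_force_on_random_networks(eps):
    rng = np.random.default_rng(12)
    for _ in range(100):
        n_r = rng.integers(2, 7)
        n_t = rng.integers(1, 9)
        regs = [f"m{i}" for i in range(n_r)]
        tgts = [f"g{j}" for j in range(n_t)]
        edges = {
            (r, t): float(np.round(rng.uniform(0.05, 1.0), 3))
            for r in regs for t in tgts if rng.random() < 0.6
        }
        if not edges:
            continue
        rr = {tuple(sorted(p)): float(np.round(rng.uniform(0.05, 1.0), 3))
              for p in itertools.combinations(regs, 2)}
        trn = _trn_from(edges, rr)
        out = apply_dpi(trn, eps=eps)
        got = set(zip(out.edges.regulator, out.edges.target))
        assert got == _brute_force_dpi(edges, rr, eps)


# ---------------------------------------------------------------------------
# infer_trn
# ---------------------------------------------------------------------------

def test_empty_inputs_give_empty_trn():
    reg = _expr(np.empty((0, 20)))
    tgt = _expr(np.random.default_rng(0).normal(size=(3, 20)), "G")
    trn = infer_trn(reg, tgt, NetInfParams(n_perm=100, n_boot=10))
    assert trn.n_edges() == 0
    assert trn.provenance["edges_after_permutation"] == 0
    assert trn.provenance["edges_after_dpi"] == 0


def test_pipeline_stages_only_shrink_edges(small_cohort):
    from mirmaster import moderated_de, select_regulators, select_targets

    coh = small_cohort
    regs = select_regulators(moderated_de(coh.mirna_expr, coh.subtype_labels))
    tgts = select_targets(moderated_de(coh.gene_expr, coh.subtype_labels))
    trn = infer_trn(coh.mirna_expr.loc[regs], coh.gene_expr.loc[tgts],
                    NetInfParams(n_perm=100, n_boot=20, seed=4))
    prov = trn.provenance
    assert prov["edges_after_permutation"] >= prov["edges_after_bootstrap"]
    assert prov["edges_after_bootstrap"] >= prov["edges_after_dpi"]
    assert prov["edges_after_dpi"] == trn.n_edges()


def test_infer_trn_deterministic_serialization(small_cohort):
    coh = small_cohort
    reg = coh.mirna_expr.iloc[:4]
    tgt = coh.gene_expr.iloc[:20]
    p = NetInfParams(n_perm=100, n_boot=10, seed=8)
    a = infer_trn(reg, tgt, p).to_json()
    b = infer_trn(reg, tgt, p).to_json()
    assert a == b


def test_trn_json_roundtrip(tmp_path, small_cohort):
    coh = small_cohort
    trn = infer_trn(coh.mirna_expr.iloc[:3], coh.gene_expr.iloc[:15],
                    NetInfParams(n_perm=100, n_boot=10, seed=8))
    path = tmp_path / "net.json"
    trn.to_json(path)
    back = TRN.from_json(path)
    pd.testing.assert_frame_equal(trn.edges, back.edges)
    pd.testing.assert_frame_equal(trn.reg_reg_mi, back.reg_reg_mi)


def test_reg_reg_mi_symmetric(small_cohort):
    rr = regulator_mi_matrix(small_cohort.mirna_expr.iloc[:5])
    np.testing.assert_allclose(rr.to_numpy(), rr.to_numpy().T)
    assert (np.diag(rr.to_numpy()) == 0).all()
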