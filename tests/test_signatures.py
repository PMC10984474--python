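"""R-index computation, signature derivation, symbol collapse, overlaps."""

import numpy as np
import pandas as pd
import pytest

from stromascape import (
    ConfigurationError,
    DegenerateInputError,
    SignatureThresholds,
    choose_anchor_probe,
    collapse_to_symbols,
    compute_cse,
    compute_r_index,
    derive_signature,
    intersect_signatures,
    normalize_by_housekeeping,
    select_top_by_amount,
)
from stromascape.signatures import SignatureDefinition
from stromascape.simulate import expected_members

from _oracles import pearson_brute
from conftest import make_matrix


def stroma_matrix(rows, probes, reference="T01_str", symbols=None):
    rows = np.asarray(rows, dtype=float)
    n_s = rows.shape[1]
    samples = [f"T{j:02d}_str" for j in range(1, n_s + 1)]
    return make_matrix(rows, probes, samples, ["stroma"] * n_s,
                       reference=reference, symbols=symbols)


def normalized(rows, probes, symbols=None, **kw):
    if symbols is not None:
        symbols = list(symbols) + ["GAPDH"]
    m = stroma_matrix(np.vstack([rows, np.full((1, np.shape(rows)[1]), 100.0)]),
                      list(probes) + ["hk"], symbols=symbols, **kw)
    return normalize_by_housekeeping(m, "hk")


def test_r_index_identity_and_negation():
    x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    nm = normalized([x, 10 - x], ["a", "neg"])
    r = compute_r_index(nm, "a")
    assert r["a"] == pytest.approx(1.0)
    assert r["neg"] == pytest.approx(-1.0)


def test_r_index_matches_brute_force_pearson():
    rng = np.random.default_rng(42)
    anchor = rng.lognormal(1, 0.5, 13)
    rows = [anchor] + [rng.lognormal(1, 0.5, 13) for _ in range(6)]
    probes = ["anchor"] + [f"p{i}" for i in range(6)]
    nm = normalized(rows, probes)
    r = compute_r_index(nm, "anchor")
    for i, p in enumerate(probes):
        expected = pearson_brute(list(rows[i]), list(anchor))
        assert r[p] == pytest.approx(expected, abs=1e-12)


def test_r_index_zero_variance_anchor_is_error():
    nm = normalized([[5.0] * 5, [1, 2, 3, 4, 5]], ["const", "p"])
    with pytest.raises(DegenerateInputError):
        compute_r_index(nm, "const")


def test_r_index_zero_variance_target_is_missing():
    nm = normalized([[1, 2, 3, 4, 5], [7.0] * 5], ["a", "const"])
    r = compute_r_index(nm, "a")
    assert np.isnan(r["const"])


def test_spearman_option_is_rank_based():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    nm = normalized([x, np.exp(x)], ["a", "mono"])
    r = compute_r_index(nm, "a", method="spearman")
    assert r["mono"] == pytest.approx(1.0)


def test_choose_anchor_probe_most_abundant_then_lexicographic():
    nm = normalized(
        [[50.0, 1, 1], [40.0, 1, 1], [40.0, 2, 2], [40.0, 3, 3]],
        ["pA", "pC", "pB", "pD"],
        symbols=["G1", "G1", "G2", "G2"],
    )
    assert choose_anchor_probe(nm, "G1") == "pA"       # 50 beats 40
    assert choose_anchor_probe(nm, "G2") == "pB"       # tie at 40 -> lexicographic
    with pytest.raises(KeyError):
        choose_anchor_probe(nm, "NOPE")


def _derive_on_synthetic(nm, truth, thresholds=SignatureThresholds()):
    profiles = compute_cse(nm)
    return derive_signature(nm, profiles, "SPARC", thresholds, name="CAFG")


def test_planted_factor_recovered_exactly(small_normalized):
    cfg, nm, truth = small_normalized
    sig = _derive_on_synthetic(nm, truth)
    planted = expected_members(truth, "CAFG")
    assert set(sig.member_probes) == set(planted)
    # every member satisfies all three inclusive filters
    assert (sig.members["r_value"] >= 0.9).all()
    assert (sig.members["cse_ratio"] >= 10).all()
    assert (sig.members["amount_ref"] >= 40).all()
    # sorted by reference amount descending
    amounts = sig.members["amount_ref"].to_numpy()
    assert (np.diff(amounts) <= 1e-12).all()


def test_raising_r_min_shrinks_membership(small_normalized):
    cfg, nm, truth = small_normalized
    base = _derive_on_synthetic(nm, truth)
    strict = _derive_on_synthetic(nm, truth, SignatureThresholds(r_min=0.95))
    assert set(strict.member_probes) <= set(base.member_probes)


def test_filters_commute(small_normalized):
    """Applying the three membership filters in any order gives the same set."""
    cfg, nm, truth = small_normalized
    profiles = compute_cse(nm)
    anchor = choose_anchor_probe(nm, "SPARC")
    r = compute_r_index(nm, anchor)
    th = SignatureThresholds()
    finite = np.isfinite(profiles["cse_ratio"]) & ~profiles["excluded"]
    masks = {
        "r": (r >= th.r_min).fillna(False),
        "cse": (finite & (profiles["cse_ratio"] >= th.cse_min)),
        "amt": profiles["amount_ref"] >= th.amount_min,
    }
    import itertools
    reference_set = None
    for order in itertools.permutations(masks):
        idx = profiles.index
        for key in order:
            idx = idx[masks[key].loc[idx]]
        if reference_set is None:
            reference_set = set(idx)
        assert set(idx) == reference_set
    sig = derive_signature(nm, profiles, "SPARC", th)
    assert set(sig.member_probes) == reference_set


def test_low_specificity_anchor_warns_but_derives(small_normalized, caplog):
    cfg, nm, truth = small_normalized
    profiles = compute_cse(nm)
    import logging
    with caplog.at_level(logging.WARNING, logger="stromascape.signatures"):
        sig = derive_signature(nm, profiles, "CD8A", name="CTLG")
    assert "fails its own cS/E filter" in caplog.text
    # the anchor (cS/E 4.7) is excluded, but its high-specificity members pass
    assert sig.anchor_probe not in sig.member_probes
    assert len(sig.members) > 0


def test_probe_set_concordance_within_noise_band(small_normalized):
    """Multiple probes of one gene generated from the same latent stay
    mutually concordant, and their R against the anchor varies by less than
    the concordance shortfall allows."""
    cfg, nm, truth = small_normalized
    tab = truth["probe_table"]
    counts = tab[tab["factor"] == "CAFG"].groupby("symbol").size()
    multi = counts[counts >= 2].index
    assert len(multi) > 0, "fixture must contain multi-probe genes"
    anchor = choose_anchor_probe(nm, "SPARC")
    r_anchor = compute_r_index(nm, anchor)
    stroma = nm.samples_in("stroma")
    for sym in multi:
        probes = list(tab.index[(tab["symbol"] == sym)])
        sub = nm.values.loc[probes, stroma].to_numpy()
        inter = np.corrcoef(sub)
        pairwise = inter[np.triu_indices(len(probes), k=1)]
        assert pairwise.min() > 0.9  # reproducible probe-set concordance
        spread = r_anchor[probes].max() - r_anchor[probes].min()
        assert spread < 1 - pairwise.min() + 0.05


def make_sig(name, entries):
    """entries: list of (probe, symbol, amount)."""
    members = pd.DataFrame(
        {
            "symbol": [e[1] for e in entries],
            "r_value": [0.95] * len(entries),
            "cse_ratio": [12.0] * len(entries),
            "amount_ref": [e[2] for e in entries],
        },
        index=pd.Index([e[0] for e in entries], name="probe_id"),
    )
    return SignatureDefinition(name=name, anchor_symbol=name, anchor_probe="p0",
                               thresholds=SignatureThresholds(), members=members)


def test_collapse_orders_symbols_by_max_probe_amount():
    sig = make_sig("S", [("pA", "geneX", 50.0), ("pB", "geneX", 45.0),
                         ("pC", "geneY", 60.0)])
    assert collapse_to_symbols(sig) == ["geneY", "geneX"]


def test_collapse_empty_signature():
    sig = make_sig("S", [])
    assert collapse_to_symbols(sig) == []


def test_collapse_matches_oracle_sort():
    rng = np.random.default_rng(5)
    entries = []
    for i in range(30):
        entries.append((f"p{i:02d}", f"g{rng.integers(0, 12):02d}",
                        float(rng.uniform(1, 100))))
    sig = make_sig("S", entries)
    got = collapse_to_symbols(sig)
    best = {}
    for _, sym, amt in entries:
        best[sym] = max(best.get(sym, -np.inf), amt)
    expected = sorted(best, key=lambda s: (-best[s], s))
    assert got == expected


@pytest.mark.parametrize(
    "n,total,expected_len",
    [(76, 115, 76), (0, 10, 0), (50, 10, 10)],
)
def test_select_top_by_amount(n, total, expected_len):
    symbols = [f"g{i:03d}" for i in range(total)]
    assert select_top_by_amount(symbols, n) == symbols[:expected_len]


def test_intersections_match_set_oracle():
    a = make_sig("CAFG", [("p1", "COL1A1", 90.0), ("p2", "PLAT", 80.0),
                          ("p3", "SPARC", 300.0), ("p4", "NNMT", 50.0)])
    b = make_sig("TAEG", [("q1", "PLAT", 70.0), ("q2", "PECAM1", 60.0),
                          ("q3", "ANXA1", 55.0)])
    c = make_sig("CTLG", [("r1", "IFNG", 45.0), ("r2", "B2M", 90.0)])
    ov = intersect_signatures([a, b, c], cafg_name="CAFG")
    table = ov.table
    sets = {
        "CAFG": {"COL1A1", "PLAT", "SPARC", "NNMT"},
        "TAEG": {"PLAT", "PECAM1", "ANXA1"},
        "CTLG": {"IFNG", "B2M"},
    }
    for name, symbols in sets.items():
        assert set(table.index[table[name]]) == symbols
    assert ov.pairwise_counts.at["CAFG", "TAEG"] == 1  # PLAT
    assert ov.pairwise_counts.at["CAFG", "CTLG"] == 0  # disjoint axes
    # fibrosis subclass: collagen prefix plus configured additions
    assert table.at["COL1A1", "subclass"] == "fibrosis"
    assert table.at["SPARC", "subclass"] == "fibrosis"
    assert table.at["NNMT", "subclass"] == "non_fibrosis"
    assert table.at["PECAM1", "subclass"] == "not_CAFG"


def test_disjoint_signatures_have_zero_overlap():
    a = make_sig("A", [("p1", "g1", 50.0)])
    b = make_sig("B", [("q1", "g2", 50.0)])
    ov = intersect_signatures([a, b])
    assert ov.pairwise_counts.at["A", "B"] == 0
    assert "subclass" not in ov.table.columns


def test_subclassing_requires_designated_cafg():
    a = make_sig("A", [("p1", "g1", 50.0)])
    b = make_sig("B", [("q1", "g2", 50.0)])
    with pytest.raises(ConfigurationError):
        intersect_signatures([a, b], cafg_name="CAFG")
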