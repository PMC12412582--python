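"""Origin typing: depth gate, diagnostic-SNP scoring, segmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyorigin.origin import (
    NOT_FAR,
    UNRESOLVED,
    WindowTrack,
    call_origin,
    classify_far_haplotype,
    extract_diagnostic_snps,
    normalize_depth,
    score_sites,
    type_origins,
    window_scores,
)
from polyorigin.simulate import FAR, NEAR1, NEAR2, RECOMBINANT
from polyorigin.windows import make_windows


def _depth_frame(means, hap_id="h1", n_windows=10):
    rows = []
    for sample, m in zip((FAR, NEAR1, NEAR2), means):
        for w in range(n_windows):
            rows.append((hap_id, sample, w * 100, (w + 1) * 100, m))
    return pd.DataFrame(rows, columns=["hap_id", "sample", "start", "end", "depth"])


# ---------------------------------------------------------------------------
# depth layer


def test_normalize_flat_track_yields_reference_constant():
    raw = _depth_frame((8.0, 8.0, 8.0))
    out = normalize_depth(raw, reference_coverage=30.0)
    assert np.allclose(out["depth"], 30.0)


def test_normalize_is_scale_invariant_per_sample(rng):
    profile = rng.uniform(1, 5, size=20)
    rows = []
    for sample, scale in ((NEAR1, 20.0), (NEAR2, 40.0)):
        for w, v in enumerate(profile):
            rows.append(("h1", sample, w, w + 1, v * scale / profile.mean()))
    raw = pd.DataFrame(rows, columns=["hap_id", "sample", "start", "end", "depth"])
    out = normalize_depth(raw)
    wide = out.pivot_table(index="start", columns="sample", values="depth")
    assert np.allclose(wide[NEAR1], wide[NEAR2])


def test_normalize_rejects_zero_depth_sample():
    raw = _depth_frame((0.0, 5.0, 5.0))
    with pytest.raises(ValueError, match="FAR"):
        normalize_depth(raw)


@pytest.mark.parametrize(
    "means, expected",
    [
        ((37.4, 0.1, 0.2), FAR),  # distant-parent reads dominate
        ((0.1, 8.8, 35.9), NOT_FAR),  # close-parent reads dominate
        ((10.0, 10.0, 10.0), UNRESOLVED),  # no discrimination
    ],
)
def test_far_gate_decision_geometry(means, expected):
    assert classify_far_haplotype(_depth_frame(means), "h1") == expected


def test_far_gate_invariant_to_uniform_rescaling():
    raw = _depth_frame((37.4, 0.1, 0.2))
    scaled = raw.assign(depth=raw["depth"] * 17.3)
    assert classify_far_haplotype(raw, "h1") == classify_far_haplotype(scaled, "h1")


def test_far_gate_warns_on_all_zero_depth():
    raw = _depth_frame((0.0, 0.0, 0.0))
    with pytest.warns(UserWarning):
        assert classify_far_haplotype(raw, "h1") == UNRESOLVED


# ---------------------------------------------------------------------------
# diagnostic SNPs


def test_extract_diagnostic_definition_and_drop_reasons():
    records = [
        ("g1", 10, ("A", "T"), ("A", "A"), ("T", "T")),  # kept
        ("g1", 20, ("A", "T"), ("A", "T"), ("T", "T")),  # het near1
        ("g1", 30, ("A", "T"), ("A", "A"), ("A", "A")),  # identical
        ("g1", 40, ("A", "T"), (None, "A"), ("T", "T")),  # missing
        ("g1", 50, ("A", "T", "C"), ("A", "A"), ("T", "T")),  # multiallelic
        ("g1", 60, ("A", "AT"), ("A", "A"), ("AT", "AT")),  # indel
        ("g2", 70, ("C", "G"), ("G", "G"), ("C", "C")),  # kept
    ]
    out = extract_diagnostic_snps(records)
    assert out.n_sites() == 2
    site = out.sites["g1"].iloc[0]
    assert (site["pos"], site["allele_near1"], site["allele_near2"]) == (10, "A", "T")
    assert out.dropped == {
        "multiallelic": 1,
        "not_snp": 1,
        "missing": 1,
        "heterozygous": 1,
        "identical": 1,
    }


def test_extract_matches_bruteforce_scan_on_simulated_parents(small_sim, tmp_path):
    """VCF round-trip extraction equals a direct site-by-site sequence scan."""
    from polyorigin import io as pio

    parents, _, _ = small_sim
    path = tmp_path / "parents.vcf"
    pio.write_parent_vcf(parents, path)
    out = extract_diagnostic_snps(pio.iter_vcf_parent_genotypes(path))
    for gid, g in parents.groups.items():
        # brute force: near parents differ and the record is biallelic,
        # i.e. the far allele coincides with one of the near alleles
        diff = g[NEAR1] != g[NEAR2]
        biallelic = (g[FAR] == g[NEAR1]) | (g[FAR] == g[NEAR2])
        expected = np.flatnonzero(diff & biallelic)
        got = out.sites[gid]["pos"].to_numpy()
        assert np.array_equal(got, expected)


def _snpset(positions, a1="A", a2="T"):
    return pd.DataFrame(
        {"pos": positions, "allele_near1": a1, "allele_near2": a2}
    )


def test_score_sites_sign_convention_and_exclusions():
    snps = _snpset([10, 20, 30])
    alleles = pd.DataFrame({"pos": [10, 20, 30], "allele": ["T", "A", "G"]})
    out = score_sites(alleles, snps)
    assert out["score"].tolist()[:2] == [1.0, -1.0]  # NEAR2 -> +1, NEAR1 -> -1
    assert np.isnan(out["score"].iloc[2])  # third allele excluded


def test_pure_near1_haplotype_scores_all_minus_one():
    snps = _snpset(list(range(0, 100, 10)))
    alleles = pd.DataFrame({"pos": snps["pos"], "allele": "A"})
    out = score_sites(alleles, snps)
    assert (out["score"] == -1.0).all()


def test_window_score_means_and_symmetry():
    scores = pd.DataFrame({"pos": [5, 15, 25, 35], "score": [1.0, 1.0, -1.0, -1.0]})
    track = window_scores(scores, span=40, window_size=40, min_sites=2)
    assert track.values[0] == 0.0
    track = window_scores(
        scores.assign(score=[1.0, 1.0, 1.0, 1.0]), span=40, window_size=40
    )
    assert track.values[0] == 1.0


@settings(derandomize=True, max_examples=100)
@given(
    n=st.integers(20, 200),
    window=st.integers(5, 400),
    seed=st.integers(0, 2**20),
)
def test_site_weighted_window_means_equal_global_mean(n, window, seed):
    """Algebraic identity: the site-count-weighted mean of window means
    equals the global mean of included site scores, to 1e-12."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(1000, size=n, replace=False))
    scores = pd.DataFrame(
        {"pos": pos, "score": rng.choice([-1.0, 1.0], size=n)}
    )
    track = window_scores(scores, span=1000, window_size=window)
    ok = track.n_sites > 0
    weighted = np.sum(track.values[ok] * track.n_sites[ok]) / track.n_sites.sum()
    assert abs(weighted - scores["score"].mean()) < 1e-12
    assert np.all(np.abs(track.values[ok]) <= 1.0)


# ---------------------------------------------------------------------------
# segmentation


def _track(values, window=10):
    vals = np.asarray(values, dtype=float)
    wins = make_windows(len(vals) * window, window)
    return WindowTrack(hap_id="h1", windows=wins, values=vals)


def test_uniform_minus_one_track_called_near1():
    call = call_origin(_track([-1.0] * 8))
    assert call.origin == NEAR1
    assert call.breakpoints == ()
    assert call.segments[0] == (0, 80, NEAR1)


def test_half_and_half_track_called_recombinant_with_mid_breakpoint():
    call = call_origin(_track([1.0] * 4 + [-1.0] * 4))
    assert call.origin == RECOMBINANT
    assert call.breakpoints == (40,)
    assert [s[2] for s in call.segments] == [NEAR2, NEAR1]
    # segments tile the haplotype
    assert call.segments[0][:2] == (0, 40) and call.segments[1][:2] == (40, 80)


def test_single_discordant_window_is_absorbed():
    call = call_origin(_track([1.0, 1.0, 1.0, -1.0, 1.0, 1.0, 1.0, 1.0]))
    assert call.origin == NEAR2
    assert call.breakpoints == ()


def test_ambiguous_windows_do_not_break_a_run():
    call = call_origin(_track([1.0, 1.0, 0.2, np.nan, 1.0, 1.0]))
    assert call.origin == NEAR2


def test_all_ambiguous_track_unresolved():
    assert call_origin(_track([0.0, 0.1, -0.2, np.nan])).origin == UNRESOLVED


def test_two_breakpoints_detected():
    call = call_origin(_track([-1.0] * 3 + [1.0] * 3 + [-1.0] * 3))
    assert call.origin == RECOMBINANT
    assert call.breakpoints == (30, 60)


def test_sign_flip_swaps_near_calls():
    vals = [1.0] * 4 + [-1.0] * 4
    a = call_origin(_track(vals))
    b = call_origin(_track([-v for v in vals]))
    assert a.origin == b.origin == RECOMBINANT
    assert a.breakpoints == b.breakpoints
    assert [s[2] for s in a.segments] == [NEAR2, NEAR1]
    assert [s[2] for s in b.segments] == [NEAR1, NEAR2]


def test_empty_track_rejected():
    with pytest.raises(ValueError):
        WindowTrack(hap_id="h1", windows=np.empty((0, 2)), values=np.empty(0))


# ---------------------------------------------------------------------------
# end-to-end typing on simulated data


def test_type_origins_recovers_truth_on_small_simulation(
    small_cfg, small_sim, small_observations
):
    from polyorigin import io as pio

    parents, offspring, truth = small_sim
    depth, alleles = small_observations
    normalized = normalize_depth(depth)
    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "parents.vcf")
        pio.write_parent_vcf(parents, path)
        snps = extract_diagnostic_snps(pio.iter_vcf_parent_genotypes(path))
    calls = type_origins(
        normalized,
        alleles,
        snps,
        {h.hap_id: h.group_id for h in offspring},
        {h.hap_id: len(h) for h in offspring},
        score_window=small_cfg.score_window,
    )
    assert len(calls) == len(offspring)
    correct = [c.origin == truth.origins[c.hap_id] for c in calls]
    assert np.mean(correct) == 1.0
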