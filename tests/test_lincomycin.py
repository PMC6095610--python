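import numpy as np
import pandas as pd
import pytest

from chlororibo import (BuildupThresholds, CoverageTrack, GeneModel,
                        SimConfig, annotate_sd, buildup_positions,
                        clearance_ratio, count_nuclear_cds, coverage_track,
                        detect_buildup_sites, match_control_sites,
                        runoff_curves, simulate_lincomycin_timecourse,
                        start_region_buildup)
from chlororibo.synthetic_data import CHLORO, build_toy_plastome, revcomp
from conftest import footprint_for_psite, make_footprints

GENOME_LEN = 4000


@pytest.fixture
def gene():
    # 900-nt ORF at [100, 1000)
    return GeneModel("g", "chloro", "+", [(100, 1000)])


def _track(counts_plus, nuclear=1_000_000, counts_minus=None):
    counts = {"+": np.zeros(GENOME_LEN, dtype=int),
              "-": np.zeros(GENOME_LEN, dtype=int)}
    for p, n in counts_plus.items():
        counts["+"][p] = n
    for p, n in (counts_minus or {}).items():
        counts["-"][p] = n
    return CoverageTrack("chloro", counts, nuclear)


def _genome_with_site(pos3p, sd="AGGAGG", gap=8, codon="ATG", strand="+"):
    """Random-free genome: all C, with a start codon whose first base is
    15 nt upstream of ``pos3p`` and an SD element ``gap`` nt above it."""
    g = ["C"] * GENOME_LEN
    if strand == "+":
        start = pos3p - 15
        g[start:start + 3] = list(codon)
        g[start - gap - len(sd):start - gap] = list(sd)
    else:
        start = pos3p + 15
        g[start - 2:start + 1] = list(revcomp(codon))
        g[start + gap + 1:start + gap + 1 + len(sd)] = list(revcomp(sd))
    return "".join(g)


# ---------------------------------------------------------------------------
# caller thresholds
# ---------------------------------------------------------------------------

def test_caller_threshold_arithmetic(gene):
    """60 RpM at t30 over 8 at t0 (7.5-fold) is called; 45 RpM or
    4.9-fold is not; t0=0 is called with the infinite-fold flag."""
    genome = _genome_with_site(700)
    t0 = _track({700: 8, 800: 13, 900: 0})
    t30 = _track({700: 60, 800: 63, 900: 55})
    sites = detect_buildup_sites([t0], [t30], [gene], genome)
    by_pos = sites.set_index("position_1based")
    assert 701 in by_pos.index
    assert by_pos.loc[701, "fold_increase"] == pytest.approx(7.5)
    assert not by_pos.loc[701, "infinite_fold"]
    assert 801 not in by_pos.index       # 63/13 = 4.85-fold: below 5
    assert by_pos.loc[901, "infinite_fold"]
    assert np.isinf(by_pos.loc[901, "fold_increase"])
    low = _track({700: 45})
    assert len(detect_buildup_sites([t0], [low], [gene], genome)) == 0


def test_annotated_start_region_never_reported(gene):
    """A 100-fold build-up whose implied P-site sits in the first seven
    codons is excluded; one codon past the region is reported."""
    genome = _genome_with_site(100 + 20 + 15)
    inside = 100 + 18 + 15      # P-site at codon 7 (last blocked codon)
    outside = 100 + 21 + 15     # P-site at codon 8
    t0 = _track({inside: 1, outside: 1})
    t30 = _track({inside: 100, outside: 100})
    sites = detect_buildup_sites([t0], [t30], [gene], genome)
    assert list(sites["position_1based"]) == [outside + 1]
    assert not sites.iloc[0]["is_annotated_start"]


def test_missing_t0_tracks_error(gene):
    with pytest.raises(ValueError, match="t=0"):
        detect_buildup_sites([], [_track({700: 60})], [gene], "C" * 100)


def test_in_frame_annotation(gene):
    genome = _genome_with_site(700)
    # implied P-site 685; gene starts at 100 -> (685-100) % 3 == 0
    t30 = _track({700: 60, 701: 60})
    sites = detect_buildup_sites([_track({700: 1, 701: 1})], [t30],
                                 [gene], genome)
    by_pos = sites.set_index("position_1based")
    assert bool(by_pos.loc[701, "in_frame_with_host"])
    assert not bool(by_pos.loc[702, "in_frame_with_host"])
    assert (by_pos["host_gene"] == "g").all()


def test_utr_site_labeled(gene):
    genome = _genome_with_site(2000)
    sites = detect_buildup_sites([_track({2000: 1})], [_track({2000: 90})],
                                 [gene], genome)
    assert sites.iloc[0]["host_gene"] == "UTR"
    assert sites.iloc[0]["in_frame_with_host"] is None


# ---------------------------------------------------------------------------
# SD / start-codon annotation
# ---------------------------------------------------------------------------

def test_sd_consensus_and_substrings():
    """AGGAGG with an 8-nt gap matches; a 4-base AGGA run matches; a
    3-base AGG run does not."""
    full = annotate_sd(_genome_with_site(700, sd="AGGAGG"), 700, "+")
    assert full["start_codon_found"] == "ATG"
    assert full["sd_match"] and full["sd_substring"] == "AGGAGG"
    four = annotate_sd(_genome_with_site(700, sd="AGGA"), 700, "+")
    assert four["sd_match"] and four["sd_substring"] == "AGGA"
    three = annotate_sd(_genome_with_site(700, sd="AGG"), 700, "+")
    assert not three["sd_match"] and three["sd_substring"] == ""


def test_gtg_start_and_minus_strand():
    res = annotate_sd(_genome_with_site(700, codon="GTG"), 700, "+")
    assert res["start_codon_found"] == "GTG"
    minus = annotate_sd(_genome_with_site(700, strand="-"), 700, "-")
    assert minus["start_codon_found"] == "ATG" and minus["sd_match"]
    assert minus["start_codon_offset"] == 15


def test_no_start_codon_in_window():
    res = annotate_sd("C" * GENOME_LEN, 700, "+")
    assert res["start_codon_found"] == "none" and not res["sd_match"]


def test_edge_truncation_flag():
    res = annotate_sd("C" * 60, 10, "+")
    assert res["edge_truncated"]


def test_sd_gap_bounds():
    """The SD must end 4-14 nt upstream of the start codon: a gap of 20
    puts it outside the searched spacer."""
    near = annotate_sd(_genome_with_site(700, gap=5), 700, "+")
    far = annotate_sd(_genome_with_site(700, gap=20), 700, "+")
    assert near["sd_match"] and not far["sd_match"]


# ---------------------------------------------------------------------------
# matched controls
# ---------------------------------------------------------------------------

def _site_frame(pos, strand="+"):
    return pd.DataFrame({"position_1based": [pos + 1], "strand": [strand]})


def test_control_proximity_rule():
    """Two in-band candidates at 600 and 2000 nt: the 600-nt one wins."""
    t0 = _track({700: 20, 1300: 22, 2700: 18})
    out = match_control_sites(_site_frame(700), [t0])
    assert out.iloc[0]["control_position_1based"] == 1301
    assert out.iloc[0]["control_band_factor"] == 2.0


def test_control_min_distance():
    """A candidate 400 nt away is ineligible; the band widens until the
    distant one qualifies."""
    t0 = _track({700: 20, 1100: 20, 2700: 300})
    out = match_control_sites(_site_frame(700), [t0])
    assert out.iloc[0]["control_position_1based"] == 2701
    assert out.iloc[0]["control_band_factor"] > 2.0


def test_control_exhaustive_oracle():
    rng = np.random.default_rng(17)
    positions = rng.choice(np.arange(50, GENOME_LEN - 50), 80,
                           replace=False)
    levels = rng.integers(1, 400, 80)
    t0 = _track(dict(zip(positions.tolist(), levels.tolist())))
    site = int(positions[0])
    out = match_control_sites(_site_frame(site), [t0])
    rpm0 = t0.rpm("+")
    target = rpm0[site]
    band = 2.0
    best = None
    while best is None:
        cands = [p for p in positions if abs(p - site) >= 500
                 and target / band <= rpm0[p] <= target * band]
        if cands:
            best = min(cands, key=lambda p: abs(p - site))
        else:
            band *= 1.5
    assert out.iloc[0]["control_position_1based"] == best + 1


# ---------------------------------------------------------------------------
# run-off curves
# ---------------------------------------------------------------------------

def _samples_from_frames(frames_by_key):
    return {k: (df, 1_000_000) for k, df in frames_by_key.items()}


def test_flat_curve_for_identical_counts(gene):
    rows = [footprint_for_psite(gene, t, 28) for t in range(30, 870, 3)]
    df = make_footprints(rows)
    samples = _samples_from_frames({("light", t, 1): df
                                    for t in (0.0, 12.0, 30.0)})
    curves = runoff_curves(samples, [gene], min_t0_rpkm=10)
    assert np.allclose(curves["percent_of_t0"], 100.0)
    assert curves["included"].all()


def test_t0_rpkm_filter(gene):
    """Body RPKM of 90 at t=0 fails the >100 filter; zero t0 excludes the
    gene entirely."""
    rows = [footprint_for_psite(gene, 30 + 3 * i, 28) for i in range(81)]
    df = make_footprints(rows)     # 81 reads / 0.9 kb / 1M nuclear = 90
    curves = runoff_curves(_samples_from_frames(
        {("light", 0.0, 1): df, ("light", 30.0, 1): df}), [gene])
    assert not curves["included"].any()
    empty = make_footprints([])
    curves0 = runoff_curves(_samples_from_frames(
        {("light", 0.0, 1): empty, ("light", 30.0, 1): empty}), [gene])
    assert len(curves0) == 0


def test_buildup_positions_excluded_from_body(gene):
    """Excluding build-up positions removes exactly their reads and never
    increases a count; the exclusion also applies at t=0."""
    body = [footprint_for_psite(gene, t, 28) for t in range(30, 870, 3)]
    site_reads = [footprint_for_psite(gene, 300, 28)] * 50
    df = make_footprints(body + site_reads)
    samples = _samples_from_frames(
        {("light", 0.0, 1): df, ("light", 30.0, 1): df})
    site_3p = int(gene.transcript_to_genomic(300)) + 15
    with_excl = runoff_curves(samples, [gene],
                              excluded_positions={"+": {site_3p}},
                              min_t0_rpkm=10)
    without = runoff_curves(samples, [gene], min_t0_rpkm=10)
    assert (with_excl["body_rpkm"] <= without["body_rpkm"]).all()
    lost = without.iloc[0]["body_rpkm"] - with_excl.iloc[0]["body_rpkm"]
    assert lost == pytest.approx(51 / 0.9)     # 50 planted + 1 body read


def test_clearance_ratio_pairs_and_omits(gene):
    curves = pd.DataFrame([
        {"gene_id": "a", "condition": "light", "timepoint_min": 30.0,
         "percent_of_t0": 40.0, "included": True},
        {"gene_id": "a", "condition": "dark", "timepoint_min": 30.0,
         "percent_of_t0": 80.0, "included": True},
        {"gene_id": "b", "condition": "light", "timepoint_min": 30.0,
         "percent_of_t0": 50.0, "included": True},
    ])
    ratios = clearance_ratio(curves)
    assert list(ratios["gene_id"]) == ["a"]
    assert ratios.iloc[0]["ratio"] == pytest.approx(2.0)


def test_caller_specificity_no_planted_sites(base_config, plastome):
    """On a light time course with no planted capture sites the caller
    returns nothing at the 50 RpM / 5-fold thresholds."""
    per_t, _ = simulate_lincomycin_timecourse(base_config, plastome,
                                              "light", [0, 30], 1)
    tracks = {}
    for t, df in per_t.items():
        nuc = count_nuclear_cds(df, plastome.nuclear_genes)
        tracks[t] = coverage_track(df, CHLORO,
                                   len(plastome.sequences[CHLORO]), nuc)
    sites = detect_buildup_sites([tracks[0.0]], [tracks[30.0]],
                                 plastome.chloro_genes,
                                 plastome.sequences[CHLORO])
    assert len(sites) == 0


# ---------------------------------------------------------------------------
# start-region build-up
# ---------------------------------------------------------------------------

def test_start_region_slopes(gene):
    """Growing start-region coverage gives a positive slope; a flat
    control gives ~zero; with one gene the metagene equals that gene."""
    start_pos = {100 + 15 + i: 10 for i in range(0, 21, 3)}
    tracks_growing = {
        float(t): _track({p: n * (1 + t) for p, n in start_pos.items()})
        for t in (0, 12, 30)}
    res = start_region_buildup(tracks_growing, [gene])
    by_gene = res.set_index("gene_id")
    assert by_gene.loc["g", "slope_sign"] == 1
    assert by_gene.loc["metagene", "slope_rpm_per_min"] == pytest.approx(
        by_gene.loc["g", "slope_rpm_per_min"])
    flat = {float(t): _track(start_pos) for t in (0, 12, 30)}
    res_flat = start_region_buildup(flat, [gene])
    assert res_flat.set_index("gene_id").loc[
        "g", "slope_rpm_per_min"] == pytest.approx(0.0)


def test_light_start_buildup_faster_than_dark(cheap_config, cheap_plastome):
    slopes = {}
    for cond in ("light", "dark"):
        per_t, _ = simulate_lincomycin_timecourse(
            cheap_config, cheap_plastome, cond, [0, 12, 30], 1)
        tracks = {}
        for t, df in per_t.items():
            nuc = count_nuclear_cds(df, cheap_plastome.nuclear_genes)
            tracks[t] = coverage_track(
                df, CHLORO, len(cheap_plastome.sequences[CHLORO]), nuc)
        res = start_region_buildup(tracks, cheap_plastome.chloro_genes)
        slopes[cond] = res.set_index("gene_id").loc["metagene",
                                                    "slope_rpm_per_min"]
    assert slopes["light"] > slopes["dark"] > 0
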