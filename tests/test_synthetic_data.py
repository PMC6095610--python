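import numpy as np
import pandas as pd
import pytest

from chlororibo import (PlantedBuildupSite, PlantedPauseSite, SimConfig,
                        build_toy_plastome, simulate_lincomycin_timecourse,
                        simulate_steady_state)
from chlororibo.synthetic_data import (CHLORO, SimulationError, revcomp)
from _oracles import walker_percent_remaining


# ---------------------------------------------------------------------------
# plastome construction
# ---------------------------------------------------------------------------

def test_plastome_layout(base_config, plastome):
    """Genes tile both strands with spacers; psbA exists; exactly one
    intron gene; genome length equals genes + spacers."""
    genes = plastome.chloro_genes
    assert len(genes) == base_config.n_genes
    assert genes[0].gene_id == "psbA"
    assert {g.strand for g in genes} == {"+", "-"}
    assert sum(g.has_intron for g in genes) == 1
    total = sum(b - a for g in genes for a, b in g.cds_segments)
    total += base_config.intron_length
    total += base_config.spacer_length * (base_config.n_genes + 1)
    assert len(plastome.sequences[CHLORO]) == total
    # segments never overlap across genes
    spans = sorted((a, b) for g in genes for a, b in g.cds_segments)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        assert b1 <= a2


def test_start_and_stop_codons_in_sequence(plastome):
    seq = plastome.sequences[CHLORO]
    for g in plastome.chloro_genes:
        cds = "".join(
            seq[a:b] if g.strand == "+" else revcomp(seq[a:b])
            for a, b in g.cds_segments)
        assert cds.startswith("ATG")
        assert cds[-3:] == "TAA"
        assert len(cds) % 3 == 0


def test_planted_sd_and_start_codon_written():
    """Planted sites carry the designed start codon at the designed
    position and the exact SD hexamer at the designed gap, both strands."""
    cfg = SimConfig(seed=4, planted_buildup_sites=[
        PlantedBuildupSite(sd_gap=5), PlantedBuildupSite(sd_gap=13),
        PlantedBuildupSite(start_codon="GTG", sd_sequence="AGGAGG")])
    pl = build_toy_plastome(cfg)
    seq = pl.sequences[CHLORO]
    assert len(pl.buildup_sites) == 3
    for site in pl.buildup_sites:
        if site.strand == "+":
            codon = seq[site.position:site.position + 3]
            sd = seq[site.position - site.sd_gap - 6:
                     site.position - site.sd_gap]
        else:
            codon = revcomp(seq[site.position - 2:site.position + 1])
            sd = revcomp(seq[site.position + site.sd_gap + 1:
                             site.position + site.sd_gap + 7])
        assert codon == site.start_codon
        assert sd == site.sd_sequence


def test_no_planted_sites_by_default(plastome):
    assert plastome.buildup_sites == []


def test_planted_site_at_annotated_start_rejected():
    cfg = SimConfig(seed=4)
    pl = build_toy_plastome(cfg)
    start = pl.chloro_genes[1].start_codon_pos
    bad = SimConfig(seed=4, planted_buildup_sites=[
        PlantedBuildupSite(position=start,
                           strand=pl.chloro_genes[1].strand)])
    with pytest.raises(SimulationError, match="collides"):
        build_toy_plastome(bad)


def test_config_validation():
    with pytest.raises(SimulationError):
        SimConfig(frame_fidelity=1.5).validate()
    with pytest.raises(SimulationError):
        SimConfig(footprint_length_distribution={28: 0.5}).validate()
    with pytest.raises(SimulationError):
        SimConfig(gene_length_range=(601, 1200)).validate()


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def test_read_count_conservation(cheap_config, cheap_plastome):
    df, truth = simulate_steady_state(cheap_config, cheap_plastome,
                                      "dark", "ribo", 1)
    chloro = int((df["seqid"] == CHLORO).sum())
    assert chloro == sum(truth.realized_counts.values())
    assert len(df) == chloro + cheap_config.nuclear_read_count


def test_fixed_seed_bit_identical(cheap_config, cheap_plastome):
    a, _ = simulate_steady_state(cheap_config, cheap_plastome, "light",
                                 "ribo", 2)
    b, _ = simulate_steady_state(cheap_config, cheap_plastome, "light",
                                 "ribo", 2)
    pd.testing.assert_frame_equal(a, b)


def test_psba_ratio_unity_when_configured(cheap_plastome):
    cfg = SimConfig(seed=11, nuclear_read_count=50_000,
                    psbA_light_dark_ratio=1.0)
    _, light = simulate_steady_state(cfg, cheap_plastome, "light", "ribo", 1)
    _, dark = simulate_steady_state(cfg, cheap_plastome, "dark", "ribo", 1)
    assert light.expected_counts["psbA"] == dark.expected_counts["psbA"]


def test_psba_ratio_realized(base_config, plastome):
    """At default depth the realized light/dark psbA count ratio sits
    within Poisson error of the configured 6-fold."""
    _, light = simulate_steady_state(base_config, plastome, "light",
                                     "ribo", 1)
    _, dark = simulate_steady_state(base_config, plastome, "dark",
                                    "ribo", 1)
    ratio = light.realized_counts["psbA"] / dark.realized_counts["psbA"]
    exp = base_config.psbA_light_dark_ratio
    # delta-method SD of a ratio of two Poisson draws
    sd = exp * np.sqrt(1 / light.expected_counts["psbA"]
                       + 1 / dark.expected_counts["psbA"])
    assert abs(ratio - exp) < 4 * sd
    for g in light.gene_ids:
        if g != "psbA":
            assert light.occupancy_per_kb[g] == dark.occupancy_per_kb[g]


def test_perfect_fidelity_psites_in_frame(cheap_plastome):
    cfg = SimConfig(seed=11, nuclear_read_count=1000, frame_fidelity=1.0)
    df, _ = simulate_steady_state(cfg, cheap_plastome, "dark", "ribo", 1)
    d3 = cfg.three_prime_offset
    for g in cheap_plastome.chloro_genes:
        sub = df[(df["seqid"] == CHLORO) & (df["strand"] == g.strand)]
        three = np.where(sub["strand"] == "+", sub["end"] - 1, sub["start"])
        psite = three - d3 if g.strand == "+" else three + d3
        t = g.genomic_to_transcript(psite)
        assert (t[t >= 0] % 3 == 0).all()


def test_pause_site_multiplies_dwell(cheap_plastome):
    cfg = SimConfig(seed=11, nuclear_read_count=1000,
                    planted_pause_sites=[
                        PlantedPauseSite("gene_02", 50, 4.0, "light")])
    _, light = simulate_steady_state(cfg, cheap_plastome, "light", "ribo", 1)
    _, dark = simulate_steady_state(cfg, cheap_plastome, "dark", "ribo", 1)
    base = 3 * light.occupancy_per_kb["gene_02"] / 1000
    # expected counts include the extra dwell only in the light
    assert light.expected_counts["gene_02"] == pytest.approx(
        dark.expected_counts["gene_02"] + 3 * base)


# ---------------------------------------------------------------------------
# lincomycin time courses
# ---------------------------------------------------------------------------

def test_zero_rate_keeps_body_occupancy(cheap_plastome):
    cfg = SimConfig(seed=11, nuclear_read_count=1000,
                    elongation_rate_light=0.0)
    per_t, truth = simulate_lincomycin_timecourse(
        cfg, cheap_plastome, "light", [0, 30], 1)
    for g, series in truth.expected_percent_remaining.items():
        assert series["30"] == pytest.approx(100.0)


def test_exhaustion_clears_body(cheap_plastome):
    """rate*t beyond the longest ORF leaves zero expected body
    occupancy."""
    cfg = SimConfig(seed=11, nuclear_read_count=1000,
                    elongation_rate_light=50.0)
    per_t, truth = simulate_lincomycin_timecourse(
        cfg, cheap_plastome, "light", [0, 30], 1)
    for g, series in truth.expected_percent_remaining.items():
        assert series["30"] == 0.0


def test_timepoint_validation(cheap_config, cheap_plastome):
    with pytest.raises(SimulationError, match="non-negative"):
        simulate_lincomycin_timecourse(cheap_config, cheap_plastome,
                                       "light", [0, -5], 1)
    with pytest.raises(SimulationError, match="include 0"):
        simulate_lincomycin_timecourse(cheap_config, cheap_plastome,
                                       "light", [12, 30], 1)


def test_halved_dark_rate_vs_walker_oracle(base_config, plastome):
    """With the dark elongation rate at half the light rate, every gene
    retains more body signal in the dark, and the simulator's expectation
    agrees with an independent per-ribosome stochastic walker."""
    rng = np.random.default_rng(123)
    truths = {}
    for cond in ("light", "dark"):
        _, truths[cond] = simulate_lincomycin_timecourse(
            base_config, plastome, cond, [0, 30], 1)
    assert truths["dark"].elongation_rate == pytest.approx(
        truths["light"].elongation_rate / 2)
    block = base_config.lincomycin_block_codon
    for g in plastome.chloro_genes:
        dark = truths["dark"].expected_percent_remaining[g.gene_id]["30"]
        light = truths["light"].expected_percent_remaining[g.gene_id]["30"]
        assert dark > light
        qlo, qhi = g.quant_transcript_window()
        for cond, expected in (("light", light), ("dark", dark)):
            est, se = walker_percent_remaining(
                g.cds_length // 3, max(block, qlo // 3), block,
                truths[cond].elongation_rate, 30.0, 40_000, rng)
            assert abs(expected - est) < max(3 * se, 0.5)


def test_capture_sites_use_initiation_lengths():
    cfg = SimConfig(seed=6, nuclear_read_count=1000,
                    planted_buildup_sites=[PlantedBuildupSite()])
    pl = build_toy_plastome(cfg)
    site = pl.buildup_sites[0]
    per_t, truth = simulate_lincomycin_timecourse(cfg, pl, "light",
                                                  [0, 30], 1)
    df = per_t[30.0]
    if site.strand == "+":
        at_site = df[(df["end"] - 1 == site.three_prime_pos) &
                     (df["strand"] == "+")]
    else:
        at_site = df[(df["start"] == site.three_prime_pos) &
                     (df["strand"] == "-")]
    init_lengths = set(cfg.initiation_length_distribution)
    elong_only = set(cfg.footprint_length_distribution) - init_lengths
    captured = truth.buildup_sites[0]["realized_captured"]
    assert captured > 0
    # the capture reads all draw initiation-mode lengths
    assert (at_site["length"].isin(init_lengths).sum()) >= captured
    assert not set(at_site["length"]) <= elong_only


def test_start_region_grows_with_time(cheap_config, cheap_plastome):
    per_t, _ = simulate_lincomycin_timecourse(
        cheap_config, cheap_plastome, "light", [0, 12, 30], 1)
    g = cheap_plastome.chloro_genes[1]
    counts = {}
    d3 = cheap_config.three_prime_offset
    for t, df in per_t.items():
        sub = df[(df["seqid"] == CHLORO) & (df["strand"] == g.strand)]
        three = np.where(sub["strand"] == "+", sub["end"] - 1,
                         sub["start"])
        psite = three - d3 if g.strand == "+" else three + d3
        tr = g.genomic_to_transcript(psite)
        counts[t] = int(((tr >= 0) & (tr < 21)).sum())
    assert counts[0.0] < counts[12.0] < counts[30.0]
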