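"""Synthetic-data generator: determinism, inheritance and round trips."""

import numpy as np
import pytest

from hybridzone import simulate
from hybridzone.classify import classify_dataset
from hybridzone.genotype import call_nuclear
from hybridzone.panel import find_diagnostic_sites, pairwise_diff_positions
from hybridzone.seqio import join_dataset
from hybridzone.simulate import (
    Ancestry,
    Cohort,
    SimParams,
    SimulationError,
    evaluate_recovery,
    generate,
    simulate_backcross_lineage,
)


def _pure_params(seed=0, n=5):
    cohorts = tuple(
        Cohort(1, "matsumoto", 2020, Ancestry.pure(t), n) for t in simulate.TAXA
    )
    return SimParams(seed=seed, cohorts=cohorts)


def test_seed_determinism_byte_identical():
    a = generate(simulate.default_scenario(seed=42, n_per_cohort=1))
    b = generate(simulate.default_scenario(seed=42, n_per_cohort=1))
    assert a.sequences == b.sequences
    assert a.metas == b.metas
    assert a.truths == b.truths
    assert a.panel.sites == b.panel.sites


def test_pure_references_recover_planted_panel():
    """Diagnostic-site discovery on error-free pure specimens returns the
    planted panel exactly (generator/recovery round trip)."""
    result = generate(_pure_params(seed=5))
    refs = {}
    for truth in result.truths:
        seq = next(
            s
            for s in result.sequences
            if s.specimen_id == truth.specimen_id and s.locus == "tyr"
        )
        refs.setdefault(truth.ancestry.mother, []).append(seq)
    recovered = find_diagnostic_sites(refs)
    assert recovered.positions == result.panel.positions
    for site in recovered.sites:
        assert site.alleles == dict(result.panel.alleles_at(site.position))


def test_planted_panel_site_pattern():
    """7/2/1 split: seven species sites, two brevipodus-private, one
    porosus-private."""
    result = generate(_pure_params(seed=6))
    assert len(pairwise_diff_positions(result.panel, "nigromaculatus", "porosus")) == 8
    assert len(pairwise_diff_positions(result.panel, "nigromaculatus", "brevipodus")) == 9
    assert len(pairwise_diff_positions(result.panel, "porosus", "brevipodus")) == 3


def test_f1_maternal_mt_and_het_at_all_species_sites():
    cohorts = (
        Cohort(1, "matsumoto", 2020, Ancestry.f1("porosus", "nigromaculatus"), 8),
    )
    result = generate(SimParams(seed=7, cohorts=cohorts))
    species_sites = set(
        pairwise_diff_positions(result.panel, "nigromaculatus", "porosus")
    )
    for truth in result.truths:
        assert truth.mt_taxon == "porosus"
        tyr = next(
            s
            for s in result.sequences
            if s.specimen_id == truth.specimen_id and s.locus == "tyr"
        )
        call = call_nuclear(tyr, result.panel)
        het_sites = {
            p for p, g in call.site_genotypes.items() if g and g[0] != g[1]
        }
        assert het_sites == species_sites


@pytest.mark.parametrize("g, expected", [(1, 0.5), (4, 0.0625)])
def test_backcross_het_frequency_matches_closed_form(g, expected):
    """Nuclear heterozygosity after g maternal backcrosses ~ (1/2)^g,
    within 3 binomial standard errors; mtDNA always the founding mother's."""
    n = 10_000
    het = 0
    for i in range(n):
        truth = simulate_backcross_lineage(g, "nigromaculatus", seed=i)
        assert truth.mt_taxon == "porosus"
        het += truth.allele_a != truth.allele_b
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(het / n - expected) <= 3 * se


def test_backcross_requires_positive_generations():
    with pytest.raises(SimulationError):
        simulate_backcross_lineage(0, "nigromaculatus", seed=1)


def test_haplotype_pool_counts_match_configuration():
    """With every variant guaranteed to be drawn, collapse yields exactly
    the configured number of distinct haplotypes."""
    from hybridzone.haplonet import collapse, mask_and_trim

    params = _pure_params(seed=8, n=400)
    result = generate(params)
    cytb = [s for s in result.sequences if s.locus == "cytb"]
    used, masked = mask_and_trim(cytb)
    table = collapse(masked, result.metas)
    configured = 3 + sum(params.minor_variants.values())
    distinct_emitted = len({s.bases for s in cytb})
    assert len(table) == distinct_emitted
    assert len(table) == configured


def test_miss_double_peak_rate_one_suppresses_all_hets():
    cohorts = (
        Cohort(1, "matsumoto", 2020, Ancestry.f1("porosus", "nigromaculatus"), 20),
    )
    params = SimParams(
        seed=9,
        cohorts=cohorts,
        miss_double_peak_rate=1.0,
        hybrid_morphology="maternal",
    )
    result = generate(params)
    for seq in result.sequences:
        if seq.locus == "tyr":
            assert not set(seq.bases) & set("RYSWKM")


def test_recovery_with_suppressed_double_peaks_counts_discordance_only():
    """With every double peak missed and hybrid morphology matching the
    maternal species, F1s are detected exactly when their suppressed
    nuclear genotype is homozygous-discordant with the mtDNA."""
    cohorts = (
        Cohort(1, "matsumoto", 2020, Ancestry.f1("porosus", "nigromaculatus"), 60),
    )
    params = SimParams(
        seed=10,
        cohorts=cohorts,
        miss_double_peak_rate=1.0,
        hybrid_morphology="maternal",
    )
    result = generate(params)
    dataset = join_dataset(result.sequences, result.metas)
    classified = classify_dataset(dataset, result.panel, result.mt_refs)
    expected_hybrid = {
        c.specimen_id
        for c in classified
        if c.nuclear_summary == "hom(nigromaculatus)"  # discordant with mt
    }
    detected = {c.specimen_id for c in classified if c.final_class == "hybrid"}
    assert detected == expected_hybrid
    metrics = evaluate_recovery(result.truths, classified)
    assert metrics.sensitivity == len(expected_hybrid) / 60


def test_invalid_params_rejected():
    with pytest.raises(SimulationError):
        SimParams(seed=1, cohorts=(), minor_freq=1.5).validate()
    with pytest.raises(SimulationError):
        SimParams(seed=1, cohorts=(), between_divergence=1).validate()
    with pytest.raises(SimulationError):
        SimParams(seed=1).validate()  # no cohorts


def test_evaluate_recovery_requires_matching_ids():
    result = generate(_pure_params(seed=14, n=2))
    dataset = join_dataset(result.sequences, result.metas)
    classified = classify_dataset(dataset, result.panel, result.mt_refs)
    with pytest.raises(SimulationError):
        evaluate_recovery(result.truths[:-1], classified)
    with pytest.raises(SimulationError):
        evaluate_recovery((), classified)


def test_write_outputs_roundtrip(tmp_path):
    from hybridzone import seqio
    from hybridzone.panel import read_panel

    result = generate(_pure_params(seed=15, n=2))
    paths = simulate.write_outputs(result, tmp_path)
    tyr = seqio.read_alignment(paths["tyr"], "tyr")
    assert len(tyr) == len(result.metas)
    metas = seqio.read_metadata(paths["metadata"])
    assert list(metas) == list(result.metas)
    panel = read_panel(paths["panel"])
    assert panel.positions == result.panel.positions
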