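from __future__ import annotations

import numpy as np
import pytest

from sigiscan import (
    DEFAULT_GENERATORS,
    Genome,
    PromoterCandidate,
    SigmaGenerator,
    SpecificityRule,
    SyntheticSpec,
    apply_specificity_rule,
    build_profile,
    classify_regulon,
    classify_regulons,
    crosstalk_matrix,
    predict_promoters,
    sample_promoter_set,
    scan_bipartite,
    simulate,
    stack_promoters,
    transfer_regulon,
)

SIGI1_RULE = SpecificityRule("sigI1", triad="CTC", offset_min=0, offset_max=0)
SIGI3_RULE = SpecificityRule("sigI3", triad="CCC", offset_min=0, offset_max=2)


def _candidate(spec_region: str, minus10: str = "CGAA", downstream: str = "TGTATT"):
    """Candidate with the given -35 region (ending in its A-tract)."""
    window = "G" * 6 + spec_region + "TGCGTGCGTGCG" + minus10 + downstream + "G" * 4
    matches = scan_bipartite(window)
    assert matches, "test construction failed to contain a match"
    return PromoterCandidate(match=matches[0])


class TestSpecificityRule:
    def test_universal_nonad_passes_sigma1_and_sigma3(self):
        """CCCCTCAAA carries CTC immediately upstream of the A-tract and CCC
        two nucleotides upstream — the universal-promoter configuration."""
        cand = _candidate("CCCCTCAAA")
        assert SIGI1_RULE.matched_offset(cand.match) == 0
        assert SIGI3_RULE.matched_offset(cand.match) == 2

    def test_ccc_free_region_fails_sigma3(self):
        assert not SIGI3_RULE.passes(_candidate("GTGATGAAA").match)

    def test_cgta_tetrad_fails_a_cgaa_rule(self):
        cand = _candidate("CCCCTCAAA", minus10="CGTA", downstream="TGTGTT")
        assert not SIGI1_RULE.passes(cand.match)
        rule_cgta = SpecificityRule("sigI3gene", triad="CCC", offset_min=0,
                                    offset_max=2, minus10_tetrad="CGTA")
        assert rule_cgta.passes(cand.match)

    def test_downstream_dyad_constraint(self):
        with_dyad = SpecificityRule("sigI1", "CTC", 0, 0, "CGAA", downstream_dyad="AT")
        good = _candidate("CCCCTCAAA", downstream="TGTATT")  # AT at positions 3-4
        bad = _candidate("CCCCTCAAA", downstream="TGTGTT")   # GT instead
        assert with_dyad.passes(good.match)
        assert not with_dyad.passes(bad.match)

    def test_filter_is_monotone_and_dyad_never_adds(self):
        cands = [_candidate("CCCCTCAAA"), _candidate("GTGATGAAA"),
                 _candidate("CCCCTCAAA", downstream="TGTGTT")]
        base = apply_specificity_rule(cands, SIGI1_RULE)
        assert set(c.key() for c in base) <= set(c.key() for c in cands)
        with_dyad = apply_specificity_rule(
            cands, SpecificityRule("sigI1", "CTC", 0, 0, "CGAA", downstream_dyad="AT")
        )
        assert set(c.key() for c in with_dyad) <= set(c.key() for c in base)

    def test_cytosine_count_variant(self):
        cands = [_candidate("CCCCTCAAA"), _candidate("GTGATGAAA")]
        kept = apply_specificity_rule(cands, SIGI3_RULE, use_c_count=True)
        assert len(kept) == 1


class TestPredictPromoters:
    def test_planted_promoters_recovered_with_gene_and_utr(self, small_benchmark):
        sspec, genome, annotations, truth = small_benchmark
        cands = predict_promoters(genome, annotations, sspec.motif, 600, "upstream_only")
        by_key = {c.key(): c for c in cands}
        for row in truth.itertuples():
            key = (row.contig, row.strand, row.atract_start, row.atract_end,
                   row.minus10_start, row.minus10_end)
            assert key in by_key, f"planted promoter missing for {row.locus_tag}"
            cand = by_key[key]
            assert cand.assigned_gene == row.locus_tag
            assert cand.utr5 == row.utr5

    def test_gene_without_motif_yields_no_candidate(self):
        genome = Genome({"c1": "G" * 800})
        from sigiscan import GeneAnnotation

        gene = GeneAnnotation("c1", 700, 790, "+", "bare")
        assert predict_promoters(genome, [gene], scope="upstream_only") == []

    def test_shared_promoter_reported_once(self):
        left = "G" * 100
        plant = "CCCCT" + "AAAA" + "TGCGTGCGTGCG" + "CGAA" + "TGTATT"
        genome = Genome({"c1": left + plant + "G" * 400})
        from sigiscan import GeneAnnotation

        near = GeneAnnotation("c1", 180, 260, "+", "near")
        far = GeneAnnotation("c1", 300, 380, "+", "far")
        cands = predict_promoters(genome, [near, far], window=600, scope="upstream_only")
        planted = [c for c in cands if c.match.atract_start == 105]
        assert len(planted) == 1
        assert planted[0].assigned_gene == "near"

    def test_upstream_candidates_subset_of_whole_genome(self, small_benchmark):
        sspec, genome, annotations, _ = small_benchmark
        upstream = predict_promoters(genome, annotations, sspec.motif, 600, "upstream_only")
        whole = predict_promoters(genome, annotations, sspec.motif, 600, "whole_genome")
        whole_keys = {c.key() for c in whole if c.assigned_gene is not None}
        assert {c.key() for c in upstream} <= whole_keys

    def test_whole_genome_assigns_nearest_downstream_gene(self, small_benchmark):
        sspec, genome, annotations, truth = small_benchmark
        whole = predict_promoters(genome, annotations, sspec.motif, 600, "whole_genome")
        by_key = {c.key(): c for c in whole}
        for row in truth.itertuples():
            key = (row.contig, row.strand, row.atract_start, row.atract_end,
                   row.minus10_start, row.minus10_end)
            cand = by_key[key]
            assert cand.assigned_gene == row.locus_tag
            assert cand.utr5 == row.utr5


class TestClassify:
    def test_universal_promoter_is_crosstalk(self, default_profiles):
        profiles, rules = default_profiles
        cand = _candidate("CCCCTCAAA")
        result = classify_regulon(cand, profiles, rules, min_score=0.0)
        assert {"sigI1", "sigI3"} <= result.assigned
        assert result.crosstalk

    def test_min_score_minus_inf_assigns_exactly_rule_passers(self, default_profiles):
        profiles, rules = default_profiles
        prof3 = {"sigI3": profiles["sigI3"]}
        rule3 = {"sigI3": rules["sigI3"]}
        for cand in [_candidate("CCCCTCAAA"), _candidate("GTGATGAAA")]:
            res = classify_regulon(cand, prof3, rule3, min_score=float("-inf"))
            assert res.assigned == ({"sigI3"} if rule3["sigI3"].passes(cand.match) else set())

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            classify_regulon(_candidate("CCCCTCAAA"), {}, {})

    def test_divergent_generators_classify_specifically(self, motif_spec):
        """Candidates sampled from a sigma-I3-style generator whose gap can
        never spell CTC are assigned to sigma-I3 alone in >=95% of draws."""
        rng = np.random.default_rng(71)
        gen3 = SigmaGenerator("sigI3", triad="CCC", gap="CY")
        gen1 = DEFAULT_GENERATORS["sigI1"]
        profiles = {}
        for gen in (gen1, gen3):
            pset = sample_promoter_set(gen, 50, rng, motif_spec)
            profiles[gen.sigma_label] = build_profile(
                stack_promoters(pset, motif_spec), pseudocount=0.5
            )
        rules = {"sigI1": gen1.rule(), "sigI3": gen3.rule()}
        specific = 0
        n_draws = 500
        for _ in range(n_draws):
            spec_seq, tetrad, downstream = gen3.sample_elements(rng)
            atract = "A" * gen3.sample_atract_length(rng)
            window = "GG" + spec_seq + atract + "TGCGTGCGTGCG" + tetrad + downstream
            cand = PromoterCandidate(match=scan_bipartite(window, motif_spec)[0])
            if classify_regulon(cand, profiles, rules).assigned == {"sigI3"}:
                specific += 1
        assert specific / n_draws >= 0.95

    def test_crosstalk_matrix_row_sums(self, default_profiles):
        profiles, rules = default_profiles
        cands = [_candidate("CCCCTCAAA"), _candidate("CTCAAA".rjust(9, "G"))]
        assignments = classify_regulons(cands, profiles, rules)
        df = crosstalk_matrix(assignments, sorted(profiles))
        for a, (_, row) in zip(assignments, df.iterrows()):
            assert row["n_assigned"] == len(a.assigned)
            assert row[list(sorted(profiles))].sum() == len(a.assigned)

    def test_crosstalk_matrix_empty(self):
        df = crosstalk_matrix([], ["sigI1", "sigI3"])
        assert list(df.columns) == ["sigI1", "sigI3", "n_assigned"]
        assert df.empty


class TestTransfer:
    def test_only_ccc_style_plants_pass_rule_stage(self, motif_spec):
        """5 sigma-I3-style plants among 50 CCC-free plants: the rule stage
        keeps exactly the 5 (the cytosine-enrichment screen)."""
        gen3 = SigmaGenerator("sigI3", triad="CCC", gap="YY")
        decoy = SigmaGenerator("decoy", triad="GTG", gap="")
        sspec = SyntheticSpec(
            seed=42,
            genome_length=80_000,
            per_sigma_plants={"sigI3": 5, "decoy": 50},
            generators={"sigI3": gen3, "decoy": decoy},
            n_decoy_genes=0,
        )
        genome, annotations, truth = simulate(sspec)
        pset = sample_promoter_set(gen3, 50, 77, motif_spec)
        profile = build_profile(stack_promoters(pset, motif_spec), pseudocount=0.5)
        report = transfer_regulon(profile, gen3.rule(), genome, annotations,
                                  sspec.motif, scope="upstream_only")
        kept_genes = {a.candidate.assigned_gene for a in report}
        sig3_genes = set(truth[truth.sigma_label == "sigI3"].locus_tag)
        assert kept_genes == sig3_genes
        scores = [a.scores["sigI3"] for a in report]
        assert scores == sorted(scores, reverse=True)

    def test_empty_target_genome_gives_empty_report(self, default_profiles, motif_spec):
        profiles, rules = default_profiles
        report = transfer_regulon(profiles["sigI3"], rules["sigI3"],
                                  Genome({"c1": "G" * 2000}), [], motif_spec)
        assert report == []
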