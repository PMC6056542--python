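from __future__ import annotations

import importlib.resources

import numpy as np
import pytest

from sigiscan import (
    DEFAULT_GENERATORS,
    MotifSpec,
    PositionProfile,
    PromoterRecord,
    PromoterSet,
    build_profile,
    consensus_string,
    read_promoter_table,
    sample_promoter_set,
    scan_bipartite,
    score_window,
    stack_promoters,
)
from sigiscan.profile import GAP


def _record(label="p", sigma="sigX", spec="CCCCT", atract="AAAA",
            spacer="G" * 13, m10="CGAATGTATT"):
    return PromoterRecord(label, sigma, spec, atract, spacer, m10)


def _pset(records):
    return PromoterSet(records[0].sigma_label, records)


class TestStack:
    def test_identical_records_give_unanimous_columns(self):
        stack = stack_promoters(_pset([_record(label=f"p{i}") for i in range(3)]))
        counted = {
            "".join(row[j] for row in stack.rows)
            for j in range(stack.width)
        }
        assert all(len(set(col)) == 1 for col in counted)

    def test_atracts_right_aligned_on_three_prime_end(self):
        stack = stack_promoters(
            _pset([_record(label="a", atract="AAA"), _record(label="b", atract="AAAAA")])
        )
        block = [j for j, r in enumerate(stack.anchor_map) if r == "atract"]
        assert len(block) == 5
        short, long = stack.rows
        assert short[block[0]] == short[block[1]] == GAP
        assert short[block[2]:block[-1] + 1] == "AAA"
        assert long[block[0]:block[-1] + 1] == "AAAAA"

    def test_width_is_sum_of_anchored_blocks(self, motif_spec):
        pset = sample_promoter_set(DEFAULT_GENERATORS["sigI3"], 20, 5, motif_spec)
        stack = stack_promoters(pset, motif_spec)
        max_atract = max(len(r.atract_seq) for r in pset.records)
        expected = (motif_spec.specificity_window + max_atract
                    + len(motif_spec.minus10_core) + motif_spec.downstream_window)
        assert stack.width == expected


class TestBuildProfile:
    def test_unanimous_columns_reach_two_bits(self):
        recs = [_record(label=f"p{i}", spec="CGA", atract="AAA", m10="CGAA")
                for i in range(4)]
        prof = build_profile(stack_promoters(_pset(recs)), pseudocount=0.0)
        ic = prof.information_content()
        assert np.allclose(ic[prof.support > 0], 2.0)

    def test_half_and_half_column_is_one_bit(self):
        recs = [_record(label="a", m10="CGAA"), _record(label="b", m10="CGAT")]
        prof = build_profile(stack_promoters(_pset(recs)), pseudocount=0.0)
        j = len(prof.anchor_map) - prof.block_widths()["minus10"] + 3  # 4th -10 column
        assert prof.information_content()[j] == pytest.approx(1.0)

    def test_columns_normalized_and_ic_bounded(self, default_profiles):
        profiles, _ = default_profiles
        for prof in profiles.values():
            assert np.allclose(prof.matrix.sum(axis=1), 1.0, atol=1e-9)
            ic = prof.information_content()
            assert (ic >= 0).all() and (ic <= 2 + 1e-9).all()

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_profile(stack_promoters(_pset([_record()])), pseudocount=-1)

    def test_sigma3_consensus_shows_ccc_triad_and_cgaa_tetrad(self, motif_spec):
        """Rebuilt sigma-I3 profiles recover the characteristic CCC triad in
        the region of specificity and the CGAA -10 tetrad."""
        pset = sample_promoter_set(DEFAULT_GENERATORS["sigI3"], 40, 9, motif_spec)
        prof = build_profile(stack_promoters(pset, motif_spec), pseudocount=0.5)
        cons = consensus_string(prof, majority_threshold=0.8)
        w = prof.block_widths()
        spec_block = cons[: w["specificity"]]
        atract_block = cons[w["specificity"]: w["specificity"] + w["atract"]]
        m10_block = cons[w["specificity"] + w["atract"]:]
        assert "CCC" in spec_block
        assert set(atract_block) == {"A"}
        assert m10_block.startswith("CGAA")


class TestConsensus:
    def test_majority_base(self):
        prof = _profile_from_columns([[1.0, 0, 0, 0]])
        assert consensus_string(prof, 0.8) == "A"

    def test_iupac_fallback(self):
        prof = _profile_from_columns([[0.5, 0, 0, 0.5]])
        assert consensus_string(prof, 0.8) == "W"

    def test_threshold_validated(self):
        prof = _profile_from_columns([[1.0, 0, 0, 0]])
        with pytest.raises(ValueError):
            consensus_string(prof, 0.2)

    def test_generating_consensus_recovered_from_samples(self, motif_spec):
        gen = DEFAULT_GENERATORS["sigI1"]
        pset = sample_promoter_set(gen, 100, 17, motif_spec)
        prof = build_profile(stack_promoters(pset, motif_spec), pseudocount=0.0)
        cons = consensus_string(prof, 0.75)
        informative = "".join(c for c, s in zip(cons, prof.support) if s > 0)
        assert informative == "CTC" + "A" * 6 + "CGAA" + "TGTATT"


def _profile_from_columns(cols):
    m = np.array(cols, dtype=float)
    return PositionProfile(
        sigma_label="x",
        matrix=m,
        anchor_map=("specificity",) * len(cols),
        background=np.full(4, 0.25),
        pseudocount=0.0,
        support=np.ones(len(cols)),
    )


class TestScoreWindow:
    def _match(self, window):
        (m,) = scan_bipartite(window, MotifSpec(minus10_core="CGAA"))
        return m

    def test_consensus_candidate_attains_column_maximum(self, sig3_profile):
        window = "G" + "CCCCT" + "AAAAAA" + "T" + "GCGTGCGTGCG" + "CGAA" + "TGTATT"
        score = score_window(sig3_profile, self._match(window))
        fmax = sig3_profile.matrix.max(axis=1)
        ceiling = sum(
            np.log2(fmax[j] / 0.25)
            for j in range(sig3_profile.width)
            if sig3_profile.support[j] > 0
        )
        assert score <= ceiling + 1e-9
        assert score >= 0.8 * ceiling  # consensus window sits near the top

    def test_random_candidates_score_below_consensus(self, sig3_profile):
        rng = np.random.default_rng(4)
        cons_window = "CCCCT" + "AAAAA" + "TGCGTGCGTGCG" + "CGAA" + "TGTATT"
        cons_score = score_window(sig3_profile, self._match(cons_window))
        scores = []
        for _ in range(200):
            spec = "".join(rng.choice(list("ACGT"), size=5))
            down = "".join(rng.choice(list("ACGT"), size=6))
            window = spec.replace("A", "C") + "AAAAA" + "TGCGTGCGTGCG" + "CGAA" + down
            scores.append(score_window(sig3_profile, self._match(window)))
        assert np.mean(scores) < cons_score

    def test_score_ignores_coordinates_and_strand(self, sig3_profile):
        from dataclasses import replace

        m = self._match("CCCCT" + "AAAA" + "TGCGTGCGTGCGT" + "CGAA" + "TGTATT")
        moved = replace(m, sequence_id="elsewhere", strand="-",
                        atract_start=m.atract_start + 1000,
                        atract_end=m.atract_end + 1000,
                        minus10_start=m.minus10_start + 1000,
                        minus10_end=m.minus10_end + 1000)
        assert score_window(sig3_profile, m) == score_window(sig3_profile, moved)


class TestParameterRecovery:
    def test_concrete_generator_recovered_exactly_at_n200(self, motif_spec):
        gen = DEFAULT_GENERATORS["sigI1"]
        pset = sample_promoter_set(gen, 200, 31, motif_spec)
        rebuilt = build_profile(stack_promoters(pset, motif_spec), pseudocount=0.0)
        target = gen.to_profile(motif_spec)
        assert rebuilt.matrix.shape == target.matrix.shape
        assert np.abs(rebuilt.matrix - target.matrix).max() <= 0.05

    def test_degenerate_columns_converge_by_lln(self, motif_spec):
        """sigma-I3's YY gap columns (true frequency 0.5 for C and T) converge
        within the 0.05 band once n is large enough for the binomial SE."""
        gen = DEFAULT_GENERATORS["sigI3"]
        pset = sample_promoter_set(gen, 2000, 37, motif_spec)
        rebuilt = build_profile(stack_promoters(pset, motif_spec), pseudocount=0.0)
        target = gen.to_profile(motif_spec)
        assert np.abs(rebuilt.matrix - target.matrix).max() <= 0.05

    def test_two_seeds_differ_but_both_converge(self, motif_spec):
        gen = DEFAULT_GENERATORS["sigI4"]
        sets = [sample_promoter_set(gen, 200, seed, motif_spec) for seed in (1, 2)]
        assert [r.spacer_seq for r in sets[0].records] != [
            r.spacer_seq for r in sets[1].records
        ]
        for pset in sets:
            rebuilt = build_profile(stack_promoters(pset, motif_spec), pseudocount=0.0)
            assert np.abs(rebuilt.matrix - gen.to_profile(motif_spec).matrix).max() <= 0.05


class TestSerialization:
    def test_profile_text_roundtrip(self, default_profiles, tmp_path):
        profiles, _ = default_profiles
        prof = profiles["sigI3"]
        path = tmp_path / "p.txt"
        prof.to_text(path)
        back = PositionProfile.from_text(path)
        assert back.sigma_label == prof.sigma_label
        assert back.anchor_map == prof.anchor_map
        assert np.allclose(back.matrix, prof.matrix, atol=1e-9)
        assert back.spacer_dist == pytest.approx(prof.spacer_dist)

    def test_single_record_with_zero_pseudocount_is_that_record(self):
        rec = _record(spec="CTC", atract="AAAA")
        prof = build_profile(stack_promoters(_pset([rec])), pseudocount=0.0)
        row = rec.specificity_seq.rjust(6, GAP)[-6:] + rec.atract_seq + rec.minus10_seq
        for j, ch in enumerate(row):
            if ch != GAP:
                assert prof.matrix[j, "ACGT".index(ch)] == 1.0


class TestFixtureTable:
    def test_shipped_synthetic_table_has_stated_motif_properties(self):
        """The bundled (synthetic) promoter table honours the documented
        anatomy: all-A A-tracts, CGAA tetrads, and the sigma-specific triads
        at their declared offsets."""
        path = importlib.resources.files("sigiscan") / "data" / "sigi_promoters.synthetic.tsv"
        sets = read_promoter_table(str(path))
        assert set(sets) == set(DEFAULT_GENERATORS)
        for label, pset in sets.items():
            gen = DEFAULT_GENERATORS[label]
            for rec in pset.records:
                assert set(rec.atract_seq) == {"A"}
                assert rec.minus10_seq.startswith(gen.tetrad)
                end = len(rec.specificity_seq) - gen.offset
                assert rec.specificity_seq[end - 3: end] == gen.triad
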