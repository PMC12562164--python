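"""Delta-PS arithmetic: containment windows, oracle equivalence, labels."""

import random

import numpy as np
import pytest

from psdelta.errors import ValidationError
from psdelta.io_formats import MissenseMutation, ProteinRecord
from psdelta.mutation_effect import (
    EffectConfig,
    apply_mutation,
    classify_effect,
    delta_ps,
    delta_ps_batch,
    mutation_window_starts,
)
from psdelta.ps_scoring import PSRegion, ScorerSpec, call_ps_regions, score_windows

from conftest import brute_force_delta, random_mutation, random_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


def _mut(acc, pos, ref, alt, sample="S1", cancer="UCEC"):
    return MissenseMutation(sample, f"G_{acc}", acc, pos, ref, alt, cancer)


class TestApplyMutation:
    def test_substitutes_single_position(self):
        assert apply_mutation(ProteinRecord("P1", "AAA"), _mut("P1", 2, "A", "G")) == "AGA"

    def test_ref_mismatch_names_letters(self):
        with pytest.raises(ValidationError, match="expected reference 'C'.*has 'A'"):
            apply_mutation(ProteinRecord("P1", "AAA"), _mut("P1", 2, "C", "G"))

    @pytest.mark.parametrize("pos", [0, 4])
    def test_out_of_range_position(self, pos):
        if pos == 0:
            with pytest.raises(ValidationError):
                _mut("P1", pos, "A", "G")
        else:
            with pytest.raises(ValidationError, match="outside"):
                apply_mutation(ProteinRecord("P1", "AAA"), _mut("P1", pos, "A", "G"))


class TestMutationWindowStarts:
    @pytest.mark.parametrize(
        "p,L,w,expected",
        [
            (50, 100, 15, list(range(36, 51))),  # interior: 15 windows
            (1, 100, 15, [1]),                   # N-terminus: 1 window
            (8, 15, 15, [1]),                    # single-window protein
            (100, 100, 15, [86]),                # C-terminus
        ],
    )
    def test_known_cases(self, p, L, w, expected):
        assert list(mutation_window_starts(p, L, w)) == expected

    def test_matches_brute_force_containment_scan(self, rng):
        for _ in range(300):
            L = rng.randrange(1, 120)
            w = rng.randrange(1, 30)
            p = rng.randrange(1, L + 1)
            got = list(mutation_window_starts(p, L, w))
            if L < w:
                expected = [1]
            else:
                expected = [
                    s for s in range(1, L - w + 2) if s <= p <= s + w - 1
                ]
            assert got == expected

    def test_n_windows_closed_form(self, rng):
        # n_windows == min(p, w, L-w+1, L-p+1) whenever L >= w
        for _ in range(300):
            L = rng.randrange(15, 120)
            w = rng.randrange(1, 16)
            p = rng.randrange(1, L + 1)
            assert len(mutation_window_starts(p, L, w)) == min(p, w, L - w + 1, L - p + 1)


class TestDeltaPs:
    def test_polyalanine_a8g_worked_example(self):
        # single window; one residue turns prone: delta = +1/15, positive
        protein = ProteinRecord("P1", "A" * 15)
        effect = delta_ps(protein, _mut("P1", 8, "A", "G"), EffectConfig())
        assert effect.wt_avg == 0.0
        assert effect.mut_avg == pytest.approx(1 / 15)
        assert effect.delta == pytest.approx(1 / 15)
        assert effect.n_windows == 1
        assert effect.affect_label == "positive"

    def test_matches_full_rescoring_oracle(self, rng):
        config = EffectConfig()
        for _ in range(200):
            protein = random_protein(rng, rng.randrange(20, 201))
            mutation = random_mutation(rng, protein)
            effect = delta_ps(protein, mutation, config)
            wt_avg, mut_avg, delta, n_win, wt_all, mut_all = brute_force_delta(
                protein, mutation, 15
            )
            assert effect.wt_avg == pytest.approx(wt_avg, abs=1e-12)
            assert effect.mut_avg == pytest.approx(mut_avg, abs=1e-12)
            assert effect.delta == pytest.approx(delta, abs=1e-12)
            assert effect.n_windows == n_win

    def test_locality_windows_outside_containment_identical(self, rng):
        config = EffectConfig()
        spec = ScorerSpec()
        for _ in range(50):
            protein = random_protein(rng, 60)
            mutation = random_mutation(rng, protein)
            mutant = ProteinRecord("P1", apply_mutation(protein, mutation))
            wt = score_windows(protein, spec).scores
            mu = score_windows(mutant, spec).scores
            containment = set(mutation_window_starts(mutation.position, 60, 15))
            for i, start in enumerate(range(1, len(wt) + 1)):
                if start not in containment:
                    assert wt[i] == mu[i]  # bit-identical

    def test_antisymmetry_on_mutated_background(self, rng):
        config = EffectConfig()
        for _ in range(100):
            protein = random_protein(rng, rng.randrange(15, 80))
            mutation = random_mutation(rng, protein)
            forward = delta_ps(protein, mutation, config)
            mutant = ProteinRecord(protein.accession, apply_mutation(protein, mutation))
            back = _mut(
                protein.accession, mutation.position, mutation.alt_aa, mutation.ref_aa
            )
            reverse = delta_ps(mutant, back, config)
            assert forward.delta == -reverse.delta  # exact float equality

    def test_prone_fraction_delta_bounded_by_one_over_w(self, rng):
        config = EffectConfig()
        for _ in range(200):
            protein = random_protein(rng, rng.randrange(15, 100))
            mutation = random_mutation(rng, protein)
            effect = delta_ps(protein, mutation, config)
            assert abs(effect.delta) <= 1 / 15 + 1e-12  # slack = mean rounding

    def test_batch_caches_equal_single_calls(self, rng):
        config = EffectConfig()
        proteins = [random_protein(rng, 60, accession=f"P{i}") for i in range(5)]
        muts = [random_mutation(rng, p) for p in proteins for _ in range(3)]
        batch = delta_ps_batch(proteins, muts, config)
        lookup = {p.accession: p for p in proteins}
        singles = [delta_ps(lookup[m.accession], m, config) for m in muts]
        assert [e.delta for e in batch] == [e.delta for e in singles]

    def test_batch_unknown_accession_raises_unless_skipped(self, rng):
        protein = random_protein(rng, 30, accession="P0")
        stray = _mut("MISSING", 1, "A", "G")
        with pytest.raises(ValidationError, match="MISSING"):
            delta_ps_batch([protein], [stray], EffectConfig())
        assert delta_ps_batch([protein], [stray], EffectConfig(), skip_unknown=True) == []


def _region(start, end, mean=0.8):
    return PSRegion("P1", start, end, mean)


class TestClassifyEffect:
    CFG = EffectConfig()

    def test_aberrant_gain_when_straddling_cutoff(self):
        labels = classify_effect(0.50, 0.55, [], [], 10, self.CFG)
        assert labels[1] == "gain"

    def test_aberrant_loss_reverse_direction(self):
        labels = classify_effect(0.55, 0.50, [], [], 10, self.CFG)
        assert labels[1] == "loss"

    def test_delta_exactly_at_cutoff_is_neutral(self):
        # strict inequality: a change of exactly 0.05 does not affect
        labels = classify_effect(0.40, 0.45, [], [], 10, self.CFG)
        assert labels[0] == "neutral"

    def test_delta_just_over_cutoff_is_positive(self):
        labels = classify_effect(0.40, 0.4501, [], [], 10, self.CFG)
        assert labels[0] == "positive"

    @pytest.mark.parametrize(
        "wt_regions,mut_regions,expected",
        [
            ([], [_region(5, 25)], "created"),
            ([_region(5, 25)], [], "lost"),
            ([_region(5, 25)], [_region(5, 30)], "extended"),
            ([_region(5, 30)], [_region(5, 25)], "contracted"),
            ([_region(5, 25)], [_region(5, 25)], "unchanged"),
        ],
    )
    def test_region_change_labels(self, wt_regions, mut_regions, expected):
        labels = classify_effect(0.4, 0.4, wt_regions, mut_regions, 10, self.CFG)
        assert labels[2] == expected

    def test_on_ps_region_flag(self):
        labels = classify_effect(0.6, 0.6, [_region(5, 25)], [_region(5, 25)], 10, self.CFG)
        assert labels[3] is True
        labels = classify_effect(0.6, 0.6, [_region(5, 25)], [_region(5, 25)], 40, self.CFG)
        assert labels[3] is False

    def test_region_created_by_planted_mutation_matches_region_diff(self):
        # below-cutoff segment lifted above the cutoff by one substitution:
        # first window holds 7/15 prone residues; A9G makes it 8/15
        seq = "G" * 7 + "A" * 33
        protein = ProteinRecord("P1", seq)
        track = score_windows(protein, ScorerSpec())
        assert call_ps_regions(track) == []  # wild type has no region
        effect = delta_ps(protein, _mut("P1", 9, "A", "G"), EffectConfig())
        assert effect.region_change == "created"

    def test_protein_flip_rule_uses_whole_protein_status(self):
        cfg = EffectConfig(aberrant_rule="protein_flip")
        labels = classify_effect(0.1, 0.2, [], [_region(5, 25)], 10, cfg)
        assert labels[1] == "gain"
        labels = classify_effect(0.9, 0.8, [_region(5, 25)], [], 10, cfg)
        assert labels[1] == "loss"

    def test_local_coverage_diff_equals_whole_protein_diff(self, rng):
        # locality: regions away from the mutation never change, so the
        # coverage change near the mutation equals the whole-protein
        # coverage change (created/lost are local refinements of it)
        config = EffectConfig()
        for _ in range(100):
            protein = random_protein(rng, rng.randrange(40, 120))
            mutation = random_mutation(rng, protein)
            effect = delta_ps(protein, mutation, config)
            mutant = ProteinRecord(protein.accession, apply_mutation(protein, mutation))
            wt_regions = call_ps_regions(score_windows(protein, ScorerSpec()))
            mut_regions = call_ps_regions(score_windows(mutant, ScorerSpec()))
            p = mutation.position
            lo, hi = p - 14, p + 14
            local_wt = sum(r.length for r in wt_regions if r.end >= lo and r.start <= hi)
            local_mut = sum(r.length for r in mut_regions if r.end >= lo and r.start <= hi)
            whole_diff = sum(r.length for r in mut_regions) - sum(r.length for r in wt_regions)
            assert local_mut - local_wt == whole_diff
            expected = (
                "extended" if whole_diff > 0 else "contracted" if whole_diff < 0 else "unchanged"
            )
            if effect.region_change in ("extended", "contracted", "unchanged"):
                assert effect.region_change == expected
            else:  # created/lost agree with the sign of the diff
                assert (effect.region_change == "created") == (whole_diff > 0)
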