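"""CAI, RCDI and SiD: identities, hand-computed values, monotone adaptation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.genetics import AA_TO_CODONS, DEGENERATE_AAS, SYNONYMOUS_CODONS
from cubkit.host_adaptation import (
    compute_cai,
    compute_rcdi,
    compute_sid,
    reference_from_counts,
    relative_adaptiveness,
)
from cubkit.rscu import RSCUVector, compute_rscu
from cubkit.sequence_io import CodonCountTable, ReferenceUsage
from conftest import random_count_table


def _full_reference(overrides: dict[str, float] | None = None) -> ReferenceUsage:
    counts = {c: 5.0 for aa in DEGENERATE_AAS for c in AA_TO_CODONS[aa]}
    counts.update(overrides or {})
    return ReferenceUsage.from_counts("ref", counts)


class TestRelativeAdaptiveness:
    def test_hand_ratio(self):
        w = relative_adaptiveness(_full_reference({"TTT": 10.0, "TTC": 5.0}))
        assert w.w["TTT"] == 1.0
        assert w.w["TTC"] == pytest.approx(0.5)

    def test_uniform_reference_all_ones(self):
        w = relative_adaptiveness(_full_reference())
        assert all(v == pytest.approx(1.0) for v in w.w.values())

    def test_zero_frequency_codon_floored_and_flagged(self):
        w = relative_adaptiveness(_full_reference({"TTC": 0.0}))
        assert w.w["TTC"] == 0.01 and "TTC" in w.smoothed

    def test_empty_family_raises_naming_amino_acid(self):
        counts = {c: 5.0 for aa in DEGENERATE_AAS for c in AA_TO_CODONS[aa]}
        for c in AA_TO_CODONS["K"]:
            counts[c] = 0.0
        with pytest.raises(ValueError, match="K"):
            relative_adaptiveness(ReferenceUsage.from_counts("ref", counts))


class TestCAI:
    def test_all_optimal_codons_score_one(self):
        w = relative_adaptiveness(_full_reference({"TTT": 10.0}))
        best = {max(AA_TO_CODONS[aa], key=lambda c: w.w[c]): 3 for aa in DEGENERATE_AAS}
        assert compute_cai(CodonCountTable(best), w) == pytest.approx(1.0, abs=1e-12)

    def test_hand_geometric_mean(self):
        w = relative_adaptiveness(_full_reference({"TTT": 10.0, "TTC": 5.0}))
        cai = compute_cai(CodonCountTable({"TTT": 1, "TTC": 1}), w)
        assert cai == pytest.approx(math.sqrt(0.5))

    def test_met_trp_not_scoreable(self):
        w = relative_adaptiveness(_full_reference())
        with pytest.raises(ValueError):
            compute_cai(CodonCountTable({"ATG": 3, "TGG": 2}), w)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_cai_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        ref = _full_reference({c: float(rng.integers(1, 30))
                               for c in SYNONYMOUS_CODONS})
        w = relative_adaptiveness(ref)
        t = random_count_table(rng)
        if sum(t.sense_counts().values()) == 0:
            return
        assert compute_cai(t, w) <= 1.0 + 1e-12


class TestRCDI:
    def test_identity_against_self_reference(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            t = random_count_table(rng, max_count=30)
            ref = reference_from_counts(t)
            assert compute_rcdi(t, ref) == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluation(self):
        rcdi = compute_rcdi(CodonCountTable({"TTT": 2}),
                            ReferenceUsage.from_counts("h", {"TTT": 1, "TTC": 1}))
        assert rcdi == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(56)
        t = random_count_table(rng, max_count=30)
        doubled = CodonCountTable({c: 2 * n for c, n in t.counts.items()})
        ref = _full_reference({"TTT": 20.0, "GCA": 1.0})
        assert compute_rcdi(t, ref) == pytest.approx(compute_rcdi(doubled, ref))

    def test_empty_query_error(self):
        with pytest.raises(ValueError):
            compute_rcdi(CodonCountTable({}), _full_reference())


class TestSiD:
    def test_self_similarity_zero(self, uniform_counts):
        v = compute_rscu(uniform_counts)
        assert compute_sid(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_proportional_vectors_zero(self):
        a = RSCUVector(values={c: 1.0 for c in SYNONYMOUS_CODONS})
        b = RSCUVector(values={c: 2.0 for c in SYNONYMOUS_CODONS})
        assert compute_sid(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_support_half(self):
        half = len(SYNONYMOUS_CODONS) // 2
        a = RSCUVector(values={c: (1.0 if i < half else 0.0)
                               for i, c in enumerate(SYNONYMOUS_CODONS)})
        b = RSCUVector(values={c: (0.0 if i < half else 1.0)
                               for i, c in enumerate(SYNONYMOUS_CODONS)})
        assert compute_sid(a, b) == pytest.approx(0.5)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(60)
        for _ in range(5):
            va = compute_rscu(random_count_table(rng, max_count=30))
            vb = compute_rscu(random_count_table(rng, max_count=30))
            d1, d2 = compute_sid(va, vb), compute_sid(vb, va)
            assert d1 == pytest.approx(d2)
            assert 0.0 <= d1 <= 1.0

    def test_zero_norm_error(self):
        z = RSCUVector(values={c: 0.0 for c in SYNONYMOUS_CODONS})
        v = RSCUVector(values={c: 1.0 for c in SYNONYMOUS_CODONS})
        with pytest.raises(ValueError):
            compute_sid(z, v)


class TestMonotoneAdaptation:
    def test_interpolating_toward_reference_improves_both_indices(self):
        """Moving a query's usage from a mismatched profile toward the
        reference profile increases CAI and decreases RCDI monotonically."""
        rng = np.random.default_rng(61)
        ref_counts = {c: float(rng.integers(1, 50))
                      for aa in DEGENERATE_AAS for c in AA_TO_CODONS[aa]}
        ref = ReferenceUsage.from_counts("host", ref_counts)
        w = relative_adaptiveness(ref)
        # mismatched start: reverse each family's reference preference
        start = {}
        for aa in DEGENERATE_AAS:
            fam = sorted(AA_TO_CODONS[aa], key=lambda c: ref_counts[c])
            for c_from, c_to in zip(fam, reversed(fam)):
                start[c_to] = ref_counts[c_from]
        scale = 10_000
        cais, rcdis = [], []
        for lam in np.linspace(0, 1, 6):
            mix = {c: int(round(scale * ((1 - lam) * start[c] + lam * ref_counts[c])))
                   for c in start}
            t = CodonCountTable(mix)
            cais.append(compute_cai(t, w))
            rcdis.append(compute_rcdi(t, ref))
        assert all(a < b + 1e-9 for a, b in zip(cais, cais[1:]))
        assert all(a > b - 1e-9 for a, b in zip(rcdis, rcdis[1:]))
        assert rcdis[-1] == pytest.approx(1.0, abs=1e-3)
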