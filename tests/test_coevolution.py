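import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allonet.alignment import GAP, SequenceWeights, cluster_weights
from allonet.coevolution import (
    BackgroundFrequencies,
    apc_correct,
    cmi_profile,
    kl_conservation,
    load_background,
    mi_matrix,
    zscore_mi,
)
from allonet.errors import InputError
from allonet.synthetic import MSASpec, synth_msa

from conftest import make_alignment
from oracles import apc_oracle, mi_entropy_oracle


def unit_weights(aln):
    return SequenceWeights(weights=np.ones(aln.n_sequences),
                           cluster_ids=np.arange(aln.n_sequences))


class TestMutualInformation:
    def test_perfectly_covarying_uniform_columns(self):
        # two identical columns uniform over {A,C,D,E}: MI = ln 4
        rows = [c * 2 for c in "ACDE" for _ in range(2)]
        aln = make_alignment(rows)
        coevo = mi_matrix(aln, pseudocount=0.0)
        assert abs(coevo.raw_mi[0, 1] - np.log(4)) < 1e-12

    def test_constant_columns_zero(self):
        aln = make_alignment(["AG"] * 6)
        coevo = mi_matrix(aln, pseudocount=0.0)
        assert coevo.raw_mi[0, 1] == 0.0

    def test_bits_base(self):
        rows = [c * 2 for c in "ACDE" for _ in range(2)]
        coevo = mi_matrix(make_alignment(rows), pseudocount=0.0, base=2)
        assert abs(coevo.raw_mi[0, 1] - 2.0) < 1e-12

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_entropy_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_seq, n_col = 6 + seed, 3 + seed % 8
        matrix = rng.integers(0, 6, size=(n_seq, n_col)).astype(np.int8)
        matrix[rng.random(matrix.shape) < 0.15] = GAP
        aln = make_alignment(
            ["".join("ACDEFG-"[min(int(v), 6)] for v in row) for row in matrix]
        )
        weights = rng.uniform(0.2, 1.0, size=n_seq)
        sw = SequenceWeights(weights=weights, cluster_ids=np.arange(n_seq))
        coevo = mi_matrix(aln, sw, pseudocount=0.0)
        for i in range(n_col):
            for j in range(i + 1, n_col):
                expect = mi_entropy_oracle(aln.matrix, weights, i, j)
                assert abs(coevo.raw_mi[i, j] - expect) < 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACDEFG-", min_size=4, max_size=4),
            min_size=3, max_size=12,
        ),
        st.floats(min_value=0.0, max_value=0.5),
    )
    def test_mi_symmetric_and_nonnegative(self, rows, pseudocount):
        aln = make_alignment(rows, ids=[f"s{i}" for i in range(len(rows))])
        coevo = mi_matrix(aln, pseudocount=pseudocount)
        assert np.array_equal(coevo.raw_mi, coevo.raw_mi.T)
        assert np.all(coevo.raw_mi >= 0.0)
        assert np.all(np.diag(coevo.raw_mi) == 0.0)

    def test_pair_with_too_few_sequences_flagged(self):
        aln = make_alignment(["A-", "-C", "A-"])
        coevo = mi_matrix(aln, pseudocount=0.0)
        assert coevo.raw_mi[0, 1] == 0.0
        assert coevo.flagged[0, 1]


class TestAPC:
    def test_two_columns_exactly_zero(self):
        rows = [c * 2 for c in "ACDE" for _ in range(2)]
        coevo = apc_correct(mi_matrix(make_alignment(rows), pseudocount=0.0))
        assert coevo.apc_mi[0, 1] == 0.0

    def test_all_zero_matrix(self):
        aln = make_alignment(["AGCD"] * 5)
        coevo = apc_correct(mi_matrix(aln, pseudocount=0.0))
        assert np.all(coevo.apc_mi == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 4 + seed
        mi = rng.uniform(0, 2, size=(n, n))
        mi = (mi + mi.T) / 2
        np.fill_diagonal(mi, 0.0)
        from allonet.coevolution import CoevolutionMatrix

        coevo = apc_correct(
            CoevolutionMatrix(raw_mi=mi, column_index=np.arange(n))
        )
        expect = apc_oracle(mi)
        assert np.allclose(coevo.apc_mi, expect, atol=1e-12)


class TestZScore:
    def test_deterministic_under_seed(self):
        aln, _ = synth_msa(MSASpec(seed=3, n_sequences=60, n_columns=8,
                                   planted_pairs=[(1, 5)]))
        a = zscore_mi(aln, n_shuffles=10, seed=42)
        b = zscore_mi(aln, n_shuffles=10, seed=42)
        assert np.array_equal(a.z_mi, b.z_mi)

    def test_planted_pair_attains_max_z(self):
        spec = MSASpec(seed=7, n_sequences=300, n_columns=20,
                       planted_pairs=[(3, 11)], coupling=0.9)
        aln, truth = synth_msa(spec)
        coevo = zscore_mi(aln, cluster_weights(aln), n_shuffles=50, seed=1)
        z = coevo.z_mi.copy()
        np.fill_diagonal(z, -np.inf)
        i, j = np.unravel_index(np.argmax(z), z.shape)
        assert {int(i), int(j)} == {3, 11}

    def test_null_alignment_z_calibrated(self):
        # i.i.d. uniform columns: |z| <= 4 for >= 99% of pairs
        rng = np.random.default_rng(5)
        rows = ["".join("ACDEFGHIKLMNPQRSTVWY"[k] for k in rng.integers(0, 20, 12))
                for _ in range(300)]
        aln = make_alignment(rows)
        coevo = zscore_mi(aln, n_shuffles=100, seed=9)
        z = coevo.z_mi[np.triu_indices(12, 1)]
        assert (np.abs(z) <= 4).mean() >= 0.99

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(InputError):
            zscore_mi(make_alignment(["ACDE"] * 4), n_shuffles=5)


class TestKLConservation:
    def test_p_equals_q_scores_zero(self):
        # one sequence per amino acid, uniform background
        rows = [c for c in "ACDEFGHIKLMNPQRSTVWY"]
        aln = make_alignment(rows)
        bg = BackgroundFrequencies(q=np.full(20, 1 / 20))
        prof = kl_conservation(aln, background=bg)
        assert abs(prof.scores[0]) < 1e-12

    def test_fully_conserved_column_closed_form(self):
        q = np.full(20, (1 - 0.0777) / 19)
        q[0] = 0.0777  # Q(A)
        bg = BackgroundFrequencies(q=q)
        aln = make_alignment(["A"] * 12)
        prof = kl_conservation(aln, background=bg)
        assert abs(prof.scores[0] - (-np.log(bg.q[0]))) < 1e-12

    def test_fully_gapped_column_flagged_zero(self):
        aln = make_alignment(["-A", "-C"])
        prof = kl_conservation(aln)
        assert prof.scores[0] == 0.0
        assert prof.flagged[0]

    def test_invariant_under_sequence_duplication(self):
        rows = ["ACDE", "ACDF", "GCDE", "AHDE"]
        aln1 = make_alignment(rows)
        aln2 = make_alignment(rows * 2, ids=[f"s{i}" for i in range(8)])
        p1 = kl_conservation(aln1, cluster_weights(aln1, 0.62))
        p2 = kl_conservation(aln2, cluster_weights(aln2, 0.62))
        assert np.allclose(p1.scores, p2.scores, atol=1e-12)

    def test_bundled_background_loads(self):
        bg = load_background()
        assert abs(bg.q.sum() - 1.0) < 1e-9
        assert bg["L"] > bg["W"]  # leucine far commoner than tryptophan


class TestCMI:
    def _coevo_with_z(self, z):
        from allonet.coevolution import CoevolutionMatrix

        n = z.shape[0]
        c = CoevolutionMatrix(raw_mi=np.zeros_like(z), column_index=np.arange(n))
        c.z_mi = z
        return c

    def test_all_below_threshold_gives_zero(self):
        z = np.full((4, 4), 5.0)
        np.fill_diagonal(z, 0)
        prof = cmi_profile(self._coevo_with_z(z), t=6.5)
        assert np.all(prof.cmi == 0.0)

    def test_single_pair_above_threshold(self):
        z = np.zeros((5, 5))
        z[1, 3] = z[3, 1] = 7.0
        prof = cmi_profile(self._coevo_with_z(z), t=6.5)
        assert prof.cmi[1] == prof.cmi[3] == 7.0
        assert prof.cmi[0] == prof.cmi[2] == prof.cmi[4] == 0.0

    def test_requires_computed_matrix(self):
        from allonet.coevolution import CoevolutionMatrix

        c = CoevolutionMatrix(raw_mi=np.zeros((3, 3)), column_index=np.arange(3))
        with pytest.raises(InputError):
            cmi_profile(c, matrix="z")
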