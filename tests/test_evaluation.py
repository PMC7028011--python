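import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jointpwm import (
    PWM,
    PWMDataset,
    across_dataset_agreement,
    agreement_set,
    column_pcc,
    columns_agree,
    external_comparison,
    gain_loss,
    jaccard_agreement_overlap,
)
from jointpwm.evaluation import threshold_sweep


def one_hot(b):
    col = np.zeros(4)
    col[b] = 1.0
    return col


AA = "ACDEFGHIKLMNPQRSTVWY"


def core(i: int) -> str:
    return AA[i % 20] * 3 + AA[i // 20]


def dataset_from_cols(cols: dict[str, np.ndarray], k=1) -> PWMDataset:
    return PWMDataset({c: PWM(v.reshape(4, -1)) for c, v in cols.items()})


UNIFORM = np.full(4, 0.25)


class TestColumnPCC:
    def test_self_correlation_is_one(self):
        u = np.array([0.7, 0.1, 0.1, 0.1])
        assert column_pcc(u, u) == pytest.approx(1.0)

    def test_orthogonal_one_hots(self):
        assert column_pcc(one_hot(0), one_hot(1)) == pytest.approx(-1 / 3)

    def test_uniform_column_is_undefined(self):
        assert np.isnan(column_pcc(UNIFORM, np.array([0.7, 0.1, 0.1, 0.1])))
        assert np.isnan(column_pcc(one_hot(0), UNIFORM))

    @settings(derandomize=True, max_examples=50)
    @given(
        scale=st.floats(0.01, 100),
        shift=st.floats(-10, 10),
        idx=st.integers(0, 9),
    )
    def test_affine_invariance(self, scale, shift, idx):
        rng = np.random.default_rng(idx)
        u = rng.dirichlet(np.ones(4))
        v = rng.dirichlet(np.ones(4))
        base = column_pcc(u, v)
        if np.isnan(base):
            return
        assert column_pcc(scale * u + shift, v) == pytest.approx(base, abs=1e-9)

    def test_symmetry(self):
        u = np.array([0.6, 0.2, 0.1, 0.1])
        v = np.array([0.1, 0.3, 0.4, 0.2])
        assert column_pcc(u, v) == column_pcc(v, u)


class TestColumnsAgree:
    def test_identical_nonuniform_agree(self):
        u = np.array([0.7, 0.1, 0.1, 0.1])
        assert columns_agree(u, u)

    def test_orthogonal_one_hots_disagree(self):
        assert not columns_agree(one_hot(0), one_hot(1))

    def test_threshold_is_inclusive(self):
        u = np.array([0.5, 0.3, 0.1, 0.1])
        v = np.array([0.4, 0.4, 0.15, 0.05])
        pcc = column_pcc(u, v)
        assert columns_agree(u, v, threshold=pcc)
        assert not columns_agree(u, v, threshold=np.nextafter(pcc, 2.0))

    def test_equal_uniform_columns_count_as_agreeing(self):
        assert columns_agree(UNIFORM, UNIFORM.copy())

    def test_uniform_vs_nonuniform_does_not_agree(self):
        assert not columns_agree(UNIFORM, one_hot(2))


class TestAcrossDatasetAgreement:
    def test_identical_datasets_fully_agree(self):
        d = dataset_from_cols({"AAAA": np.array([0.7, 0.1, 0.1, 0.1]), "CCCC": one_hot(1)})
        rep = across_dataset_agreement(d, d)
        assert rep.fraction_agreeing == 1.0
        assert rep.median_pcc == pytest.approx(1.0)
        assert rep.n_undefined_pcc == 0

    def test_orthogonal_one_hots_never_agree(self):
        d1 = dataset_from_cols({"AAAA": one_hot(0), "CCCC": one_hot(2)})
        d2 = dataset_from_cols({"AAAA": one_hot(1), "CCCC": one_hot(3)})
        rep = across_dataset_agreement(d1, d2)
        assert rep.fraction_agreeing == 0.0
        assert rep.median_pcc == pytest.approx(-1 / 3)

    def test_uniform_pairs_counted_separately(self):
        d1 = dataset_from_cols({"AAAA": UNIFORM.copy(), "CCCC": one_hot(0)})
        d2 = dataset_from_cols({"AAAA": one_hot(1), "CCCC": one_hot(0)})
        rep = across_dataset_agreement(d1, d2)
        assert rep.n_undefined_pcc == 1
        assert rep.n_pairs == 1
        assert rep.fraction_agreeing == 1.0

    def test_random_pairing_is_reproducible(self):
        rng = np.random.default_rng(16)
        cols1 = {c * 4: rng.dirichlet(np.ones(4)) for c in "ACDEFG"}
        cols2 = {c: rng.dirichlet(np.ones(4)) for c in cols1}
        d1, d2 = dataset_from_cols(cols1), dataset_from_cols(cols2)
        r1 = across_dataset_agreement(d1, d2, pairing_kind="random", seed=5)
        r2 = across_dataset_agreement(d1, d2, pairing_kind="random", seed=5)
        assert r1.pccs == r2.pccs

    def test_empty_intersection_errors(self):
        d1 = dataset_from_cols({"AAAA": one_hot(0)})
        d2 = dataset_from_cols({"CCCC": one_hot(0)})
        with pytest.raises(ValueError, match="share no core"):
            across_dataset_agreement(d1, d2)


class TestGainLoss:
    @pytest.fixture
    def toy(self):
        """4 corresponding pairs: 2 initially agreeing, 2 disagreeing."""
        peak = np.array([0.7, 0.1, 0.1, 0.1])
        init1 = dataset_from_cols(
            {"AAAA": peak, "CCCC": peak, "GGGG": one_hot(0), "TTTT": one_hot(2)}
        )
        init2 = dataset_from_cols(
            {"AAAA": peak, "CCCC": peak, "GGGG": one_hot(1), "TTTT": one_hot(3)}
        )
        # revision brings both disagreeing pairs into agreement, keeps the rest
        rev1 = dataset_from_cols(
            {"AAAA": peak, "CCCC": peak, "GGGG": one_hot(1), "TTTT": one_hot(3)}
        )
        return init1, init2, rev1, init2

    def test_no_revision_means_no_swaps(self, toy):
        init1, init2, _, _ = toy
        rep = gain_loss(init1, init2, init1, init2)
        assert rep.gain == 0.0 and rep.loss == 0.0
        assert rep.enrichment is None

    def test_constructed_full_gain_no_loss(self, toy):
        init1, init2, rev1, rev2 = toy
        rep = gain_loss(init1, init2, rev1, rev2)
        assert rep.gain == 1.0 and rep.loss == 0.0
        assert rep.n_initially_agreeing == 2 and rep.n_initially_disagreeing == 2

    def test_swapping_roles_swaps_gain_and_loss(self, toy):
        init1, init2, rev1, rev2 = toy
        fwd = gain_loss(init1, init2, rev1, rev2)
        back = gain_loss(rev1, rev2, init1, init2)
        assert back.n_gained == fwd.n_lost
        assert back.n_lost == fwd.n_gained

    def test_partition_sizes_bound_fractions(self):
        rng = np.random.default_rng(17)
        cols = lambda: {core(i): rng.dirichlet(np.ones(4)) for i in range(9)}
        reps = [dataset_from_cols(cols()) for _ in range(4)]
        rep = gain_loss(*reps)
        for frac in (rep.gain, rep.loss):
            assert frac is None or 0 <= frac <= 1
        assert rep.n_initially_agreeing + rep.n_initially_disagreeing == 9


class TestJaccard:
    def test_equal_nonempty_sets(self):
        s = {("AAAA", 0), ("CCCC", 1)}
        assert jaccard_agreement_overlap(s, set(s)) == 1.0

    def test_disjoint_sets(self):
        assert jaccard_agreement_overlap({("AAAA", 0)}, {("CCCC", 0)}) == 0.0

    def test_partial_overlap(self):
        a = {("A", 0), ("B", 0), ("C", 0)}
        b = {("A", 0), ("B", 0), ("C", 0), ("D", 0)}
        assert jaccard_agreement_overlap(a, b) == 0.75

    def test_both_empty_convention(self):
        assert jaccard_agreement_overlap(set(), set()) == 1.0


class TestExternalComparison:
    def test_no_revision_gives_zero_delta(self):
        rng = np.random.default_rng(18)
        cols = {core(i): rng.dirichlet(np.ones(4)) for i in range(6)}
        ext = dataset_from_cols({c: rng.dirichlet(np.ones(4)) for c in cols})
        d = dataset_from_cols(cols)
        rep = external_comparison(d, ext, d, seed=1)
        assert rep.delta == 0.0

    def test_perfect_revision_from_orthogonal_start(self):
        ext = dataset_from_cols({"AAAA": one_hot(0), "CCCC": one_hot(1)})
        initial = dataset_from_cols({"AAAA": one_hot(1), "CCCC": one_hot(2)})
        rep = external_comparison(ext, ext, initial, seed=1)
        assert rep.fraction_revised == 1.0
        assert rep.fraction_initial == 0.0
        assert rep.delta == 1.0

    def test_control_reproducible(self):
        rng = np.random.default_rng(19)
        cols = {core(i): rng.dirichlet(np.ones(4)) for i in range(8)}
        ext = dataset_from_cols({c: rng.dirichlet(np.ones(4)) for c in cols})
        d = dataset_from_cols(cols)
        r1 = external_comparison(d, ext, d, seed=7)
        r2 = external_comparison(d, ext, d, seed=7)
        assert r1.fraction_revised_random_control == r2.fraction_revised_random_control

    def test_disjoint_cores_error(self):
        d = dataset_from_cols({"AAAA": one_hot(0)})
        ext = dataset_from_cols({"CCCC": one_hot(0)})
        with pytest.raises(ValueError, match="external"):
            external_comparison(d, ext, d)


class TestAgreementSetAndSweep:
    def test_agreement_set_matches_report(self):
        rng = np.random.default_rng(20)
        cols1 = {core(i): rng.dirichlet(np.ones(4)) for i in range(10)}
        cols2 = {c: rng.dirichlet(np.ones(4)) for c in cols1}
        d1, d2 = dataset_from_cols(cols1), dataset_from_cols(cols2)
        agr = agreement_set(d1, d2)
        rep = across_dataset_agreement(d1, d2)
        assert len(agr) == round(rep.fraction_agreeing * rep.n_pairs)

    def test_fraction_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(21)
        cols1 = {core(i): rng.dirichlet(np.ones(4)) for i in range(30)}
        cols2 = {c: 0.7 * v + 0.3 * rng.dirichlet(np.ones(4)) for c, v in cols1.items()}
        cols2 = {c: v / v.sum() for c, v in cols2.items()}
        sweep = threshold_sweep(dataset_from_cols(cols1), dataset_from_cols(cols2))
        vals = [sweep[t] for t in sorted(sweep)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))
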