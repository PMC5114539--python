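"""Testlet selection and the adaptive administration loop."""

import numpy as np
import pytest

import testmat as tm
from testmat.information import expanded_information


def make_state(pool, answered, theta_hat, gamma_hat, variances, rng):
    """Build a PersonState with `answered` testlets filled with random responses."""
    state = tm.PersonState(
        pool=pool,
        prior=tm.expand_prior(tm.STUDY_PHI[: pool.P, : pool.P], [variances[t] for t in answered]),
        theta_hat=np.asarray(theta_hat, float),
        gamma_hat=np.asarray(gamma_hat, float),
    )
    for slot, tid in enumerate(answered):
        state.administered.append(tid)
        for i in pool.testlet_members[tid]:
            state.item_indices.append(int(i))
            state.responses.append(int(rng.integers(2)))
            state._A.append(pool.A[i])
            state._b.append(float(pool.b[i]))
            state._c.append(float(pool.c[i]))
            state._slot.append(slot)
    return state


def brute_force_best(state):
    """Independent oracle: evaluate det(Phi_v^-1 + I_v + I_cand) per candidate."""
    pool = state.pool
    P = pool.P
    answered_items = [pool.items[i] for i in state.item_indices]
    gamma_map = dict(zip(state.administered, state.gamma_hat))
    I_v = expanded_information(state.theta_hat, gamma_map, answered_items)
    base = state.prior.precision() + I_v
    dets = {}
    for tid in state.remaining_testlets():
        items = [pool.items[i] for i in pool.testlet_members[tid]]
        cand = tm.testlet_information(state.theta_hat, items)
        M = base.copy()
        M[:P, :P] += cand
        dets[tid] = np.linalg.det(M)
    best = max(dets, key=lambda t: (dets[t], -pool.testlet_ids.index(t)))
    # ties: lowest pool order
    top = max(dets.values())
    for tid in pool.testlet_ids:
        if tid in dets and dets[tid] >= top - 1e-12 * abs(top):
            return tid, dets
    return best, dets


class TestMATSelection:
    def test_agrees_with_brute_force_enumeration(self, small_pool):
        rng = np.random.default_rng(99)
        variances = {t: 0.7 for t in small_pool.testlet_ids}
        for trial in range(25):
            n_ans = int(rng.integers(0, 4))
            answered = list(rng.choice(small_pool.testlet_ids, size=n_ans, replace=False))
            state = make_state(
                small_pool,
                answered,
                rng.normal(size=3),
                rng.normal(scale=0.5, size=n_ans),
                variances,
                rng,
            )
            chosen, _ = tm.select_next_testlet_mat(state)
            oracle, _ = brute_force_best(state)
            assert chosen == oracle, f"trial {trial}: {chosen} vs {oracle}"

    def test_unidimensional_candidates_prefer_matched_difficulty(self):
        # P=1, prior N(0,1), Rasch candidates at b=0 and b=3, theta_hat=0:
        # determinants 1.25 vs ~1.045, so the matched item wins
        items = [
            tm.Item(id="a", a=np.array([1.0]), b=0.0, testlet_id="t_easy"),
            tm.Item(id="b", a=np.array([1.0]), b=3.0, testlet_id="t_hard"),
        ]
        pool = tm.ItemPool(items)
        state = tm.PersonState(
            pool=pool,
            prior=tm.expand_prior(np.eye(1)),
            theta_hat=np.zeros(1),
            gamma_hat=np.zeros(0),
        )
        chosen, scores = tm.select_next_testlet_mat(state)
        assert chosen == "t_easy"
        assert np.exp(scores[0]) == pytest.approx(1.25, abs=1e-6)

    def test_dominating_candidate_always_chosen(self):
        # identical structure, one candidate strictly more informative
        items = [
            tm.Item(id="a", a=np.array([1.0, 0.0]), b=0.0, testlet_id="good"),
            tm.Item(id="b", a=np.array([1.0, 0.0]), b=4.0, testlet_id="weak"),
        ]
        pool = tm.ItemPool(items)
        state = tm.PersonState(
            pool=pool,
            prior=tm.expand_prior(np.eye(2)),
            theta_hat=np.zeros(2),
            gamma_hat=np.zeros(0),
        )
        chosen, _ = tm.select_next_testlet_mat(state)
        assert chosen == "good"

    def test_exhausted_pool_rejected(self, small_pool):
        rng = np.random.default_rng(1)
        variances = {t: 0.5 for t in small_pool.testlet_ids}
        state = make_state(
            small_pool, list(small_pool.testlet_ids), np.zeros(3), np.zeros(5), variances, rng
        )
        with pytest.raises(ValueError, match="candidate"):
            tm.select_next_testlet_mat(state)


class TestRANSelection:
    def test_single_remaining_testlet_is_forced(self, small_pool):
        rng = np.random.default_rng(2)
        variances = {t: 0.5 for t in small_pool.testlet_ids}
        state = make_state(
            small_pool, small_pool.testlet_ids[:4], np.zeros(3), np.zeros(4), variances, rng
        )
        assert tm.select_next_testlet_ran(state, rng) == small_pool.testlet_ids[4]

    def test_uniform_over_remaining(self, small_pool):
        rng = np.random.default_rng(3)
        variances = {t: 0.5 for t in small_pool.testlet_ids}
        state = make_state(small_pool, small_pool.testlet_ids[:1], np.zeros(3), np.zeros(1), variances, rng)
        counts = {t: 0 for t in state.remaining_testlets()}
        for _ in range(10_000):
            counts[tm.select_next_testlet_ran(state, rng)] += 1
        for t, n in counts.items():
            assert n / 10_000 == pytest.approx(0.25, abs=0.02)


class TestAdminister:
    @pytest.fixture()
    def truth(self, pool3):
        rng = np.random.default_rng(17)
        theta = rng.normal(size=3)
        gamma = {t: float(rng.normal(scale=0.7)) for t in pool3.testlet_ids}
        return theta, gamma

    def test_size3_pool_gives_18_testlets(self, pool3, truth):
        rng = np.random.default_rng(5)
        variances = {t: 0.5 for t in pool3.testlet_ids}
        rec = tm.administer(truth, pool3, tm.CATConfig(), tm.STUDY_PHI, variances, rng)
        assert len(rec.testlets) == 18
        assert len(rec.responses) == 54
        assert len(set(rec.testlets)) == 18  # no testlet twice
        assert len(rec.provisional_theta) == 18
        assert rec.gamma_hat.shape == (18,)

    def test_size9_pool_gives_6_testlets(self, study_pool_params, truth):
        pool9 = study_pool_params.pool(9)
        rng = np.random.default_rng(5)
        variances = {t: 1.5 for t in pool9.testlet_ids}
        rec = tm.administer(truth, pool9, tm.CATConfig(), tm.STUDY_PHI, variances, rng)
        assert len(rec.testlets) == 6

    def test_mirt_model_never_adds_gamma_dimensions(self, pool3, truth):
        rng = np.random.default_rng(5)
        variances = {t: 0.5 for t in pool3.testlet_ids}
        rec = tm.administer(
            truth, pool3, tm.CATConfig(model="MIRT"), tm.STUDY_PHI, variances, rng
        )
        assert rec.gamma_hat.shape == (0,)
        assert all(g.shape == (0,) for g in rec.provisional_gamma)

    def test_indivisible_test_length_rejected(self, pool3, truth):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="multiple"):
            tm.administer(
                truth, pool3, tm.CATConfig(max_items=50), tm.STUDY_PHI,
                {t: 0.5 for t in pool3.testlet_ids}, rng,
            )

    def test_seeded_runs_are_bit_reproducible(self, pool3, truth):
        variances = {t: 1.0 for t in pool3.testlet_ids}
        recs = []
        for _ in range(2):
            rng = np.random.default_rng(777)
            recs.append(
                tm.administer(truth, pool3, tm.CATConfig(), tm.STUDY_PHI, variances, rng)
            )
        a, b = recs
        assert a.testlets == b.testlets
        assert a.responses == b.responses
        assert np.array_equal(a.theta_hat, b.theta_hat)
        assert np.array_equal(a.gamma_hat, b.gamma_hat)

    def test_responses_come_from_generating_pool_not_scoring_pool(self, pool3, truth):
        # score with absurdly hard rescaled difficulties while generating
        # from the true pool: responses must reflect the generating pool
        rng = np.random.default_rng(13)
        hard = tm.rescale_difficulties(pool3, 1.0)
        hard = tm.ItemPool(
            [tm.Item(it.id, it.a, it.b + 50.0, it.c, it.testlet_id) for it in hard.items]
        )
        variances = {t: 0.5 for t in pool3.testlet_ids}
        rec = tm.administer(
            truth, hard, tm.CATConfig(selection="RAN"), tm.STUDY_PHI, variances,
            rng, response_pool=pool3,
        )
        assert sum(rec.responses) > 0  # impossible under the +50 difficulties
        with pytest.raises(ValueError, match="same items"):
            tm.administer(
                truth, pool3, tm.CATConfig(), tm.STUDY_PHI, variances, rng,
                response_pool=tm.ItemPool([pool3.items[0]]),
            )

    def test_ran_without_replacement(self, pool3, truth):
        rng = np.random.default_rng(9)
        variances = {t: 0.5 for t in pool3.testlet_ids}
        rec = tm.administer(
            truth, pool3, tm.CATConfig(selection="RAN"), tm.STUDY_PHI, variances, rng
        )
        assert len(set(rec.testlets)) == len(rec.testlets)


class TestResponseSet:
    def test_stacking_preserves_structure(self, pool3):
        rng = np.random.default_rng(21)
        variances = {t: 0.5 for t in pool3.testlet_ids}
        theta = rng.normal(size=(3, 3))
        records = []
        for j in range(3):
            gmap = {t: float(rng.normal(scale=0.5)) for t in pool3.testlet_ids}
            records.append(
                tm.administer(
                    (theta[j], gmap), pool3, tm.CATConfig(), tm.STUDY_PHI, variances, rng
                )
            )
        data = tm.build_response_set(records, pool3)
        assert data.item_idx.shape == (3, 54)
        assert data.person_testlets.shape == (3, 18)
        for j, rec in enumerate(records):
            np.testing.assert_array_equal(data.responses[j], rec.responses)
        assert data.testlet_exposure().sum() == 3 * 18
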