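"""Permutation-test contracts: exactness against exhaustive enumeration,
type-I calibration on null genes, determinism, and two-sidedness."""

from itertools import combinations

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

import iodecon as io
from iodecon.cohort import CohortData
from iodecon.deconvolve import COMPARTMENTS


def oracle_statistic(e, p, mask, compartment):
    """Independent statistic: scipy NNLS per group + predicted-mean SE."""

    def group(eg, pg):
        X = np.column_stack([pg, 1 - pg])
        coef, _ = scipy_nnls(X, eg)
        resid = eg - X @ coef
        n = len(eg)
        mse = (resid @ resid) / (n - 2) if n > 2 else 0.0
        pbar = pg.mean()
        sxx = ((pg - pbar) ** 2).sum()
        se_c = np.sqrt(mse * (1 / n + (1 - pbar) ** 2 / sxx))
        se_s = np.sqrt(mse * (1 / n + pbar**2 / sxx))
        return coef, se_c, se_s

    (ca, sa), se_ca, se_sa = group(e[mask], p[mask])
    (cb, sb), se_cb, se_sb = group(e[~mask], p[~mask])
    if compartment == io.CANCER:
        delta, den = ca - cb, np.hypot(se_ca, se_cb)
    else:
        delta, den = sa - sb, np.hypot(se_sa, se_sb)
    if den == 0:
        return delta, 0.0 if delta == 0 else np.sign(delta) * np.inf
    return delta, delta / den


def exhaustive_p(e, p, labels, compartment):
    """Exact two-sided p over all distinct group assignments."""
    n = len(labels)
    obs_mask = labels == io.RESPONDER
    k = int(obs_mask.sum())
    _, t_obs = oracle_statistic(e, p, obs_mask, compartment)
    count = total = 0
    for idx in combinations(range(n), k):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        _, t = oracle_statistic(e, p, mask, compartment)
        count += abs(t) >= abs(t_obs)
        total += 1
    return count / total


def _mini_cohort(rng, n=20, resp_frac=0.5, stroma_shift=0.0, cancer_shift=0.0, sigma=0.3):
    """Expression generated additively on the model scale:
    e = p*c + (1-p)*s + noise, with group shifts applied to planted means."""
    p = rng.beta(5, 3, n)
    resp = np.zeros(n, bool)
    resp[rng.permutation(n)[: int(resp_frac * n)]] = True
    c = 6.0 + cancer_shift * resp
    s = 3.0 + stroma_shift * resp
    e = c * p + s * (1 - p) + rng.normal(0, sigma, n)
    labels = np.where(resp, io.RESPONDER, io.NONRESPONDER)
    return e, p, labels


class TestObservedStatistic:
    def test_identical_groups_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 12)
        e = 5.0 * p + 2.0 * (1 - p)
        labels = np.array([io.RESPONDER] * 6 + [io.NONRESPONDER] * 6)
        for comp in COMPARTMENTS:
            delta, t = io.observed_statistic(e, p, labels, comp)
            assert delta == pytest.approx(0.0, abs=1e-9)
            assert t == pytest.approx(0.0, abs=1e-6)

    def test_planted_stromal_shift_recovered(self, rng):
        """Noiseless +1 stromal effect: stroma delta exactly 1, cancer 0."""
        p = rng.uniform(0.1, 0.9, 16)
        resp = np.arange(16) < 8
        s = 3.0 + 1.0 * resp
        e = 6.0 * p + s * (1 - p)
        labels = np.where(resp, io.RESPONDER, io.NONRESPONDER)
        delta_s, _ = io.observed_statistic(e, p, labels, io.STROMA)
        delta_c, _ = io.observed_statistic(e, p, labels, io.CANCER)
        assert delta_s == pytest.approx(1.0, abs=1e-9)
        assert delta_c == pytest.approx(0.0, abs=1e-9)

    def test_zero_se_nonzero_delta_is_infinite(self, rng):
        p = rng.uniform(0.1, 0.9, 12)
        resp = np.arange(12) < 6
        e = 6.0 * p + (3.0 + resp) * (1 - p)  # exact fits in both groups
        labels = np.where(resp, io.RESPONDER, io.NONRESPONDER)
        _, t = io.observed_statistic(e, p, labels, io.STROMA)
        assert np.isinf(t) and t > 0


class TestPermutationTest:
    def test_null_statistic_gives_p_one(self, rng):
        """Group labels duplicated onto identical data: T_obs is exactly 0,
        so every permuted |T*| >= |T_obs| and p = 1."""
        p_half = rng.uniform(0.1, 0.9, 6)
        e_half = rng.normal(4.0, 1.0, 6)
        p = np.r_[p_half, p_half]
        e = np.r_[e_half, e_half]
        labels = np.array([io.RESPONDER] * 6 + [io.NONRESPONDER] * 6)
        for res in io.permutation_test(e, p, labels, n_perm=200, seed=1):
            assert res.delta == 0.0
            assert res.p_value == 1.0

    def test_smallest_attainable_p(self, rng):
        """Noiseless group shift: T_obs infinite, no permuted split matches,
        p hits the add-one floor 1/(n_perm+1)."""
        p = rng.uniform(0.1, 0.9, 16)
        resp = np.arange(16) < 8
        e = 6.0 * p + (3.0 + 2.0 * resp) * (1 - p)
        labels = np.where(resp, io.RESPONDER, io.NONRESPONDER)
        res = {r.compartment: r for r in io.permutation_test(e, p, labels, n_perm=200, seed=2)}
        assert res[io.STROMA].p_value == pytest.approx(1 / 201)

    def test_matches_exhaustive_enumeration_4v4(self, rng):
        """Monte-Carlo p within 3 MC SEs of the exact p over all 70 splits."""
        n_perm = 2000
        for trial in range(3):
            e, p, labels = _mini_cohort(rng, n=8, resp_frac=0.5, stroma_shift=1.0, sigma=0.5)
            results = {r.compartment: r for r in io.permutation_test(e, p, labels, n_perm=n_perm, seed=trial)}
            for comp in COMPARTMENTS:
                exact = exhaustive_p(e, p, labels, comp)
                se = np.sqrt(exact * (1 - exact) / n_perm) + 1 / n_perm
                assert abs(results[comp].p_value - exact) <= 3 * se + 1e-12

    def test_determinism_and_label_swap_invariance(self, rng):
        e, p, labels = _mini_cohort(rng, n=20, stroma_shift=0.8)
        a = io.permutation_test(e, p, labels, n_perm=300, seed=5)
        b = io.permutation_test(e, p, labels, n_perm=300, seed=5)
        assert [r.p_value for r in a] == [r.p_value for r in b]
        swapped = np.where(labels == io.RESPONDER, io.NONRESPONDER, io.RESPONDER)
        c = io.permutation_test(e, p, swapped, n_perm=300, seed=5)
        for ra, rc in zip(a, c):
            assert ra.p_value == rc.p_value
            assert rc.delta == pytest.approx(-ra.delta)

    def test_invalid_arguments(self, rng):
        e, p, labels = _mini_cohort(rng, n=12)
        with pytest.raises(ValueError, match="n_perm"):
            io.permutation_test(e, p, labels, n_perm=0)
        bad = np.array([io.RESPONDER] + [io.NONRESPONDER] * 11)
        with pytest.raises(ValueError, match="at least 2"):
            io.permutation_test(e, p, bad, n_perm=10)


class TestCohortDE:
    def _null_cohort(self, rng, n_genes=300, n=60):
        p = rng.beta(5, 3, n)
        E = 6.0 * p + 3.0 * (1 - p) + rng.normal(0, 0.3, (n_genes, n))
        labels = np.array([io.RESPONDER] * (n // 2) + [io.NONRESPONDER] * (n - n // 2))
        samples = [f"s{i}" for i in range(n)]
        import pandas as pd

        return CohortData(
            cohort_id="null",
            expression=pd.DataFrame(E, index=[f"g{i}" for i in range(n_genes)], columns=samples),
            purity=pd.Series(p, index=samples),
            response=pd.Series(labels, index=samples),
        )

    def test_reruns_deterministic_and_sorted(self, rng):
        cohort = self._null_cohort(rng, n_genes=20, n=20)
        a = io.cohort_de(cohort, n_perm=100, seed=9)
        b = io.cohort_de(cohort, n_perm=100, seed=9)
        assert a.equals(b)
        assert list(a["gene_id"]) == sorted(a["gene_id"])

    def test_type_i_error_quick(self, rng):
        """Null rejection rate at alpha = 0.1 within the binomial 99% band."""
        from scipy.stats import binom

        cohort = self._null_cohort(rng, n_genes=300, n=60)
        table = io.cohort_de(cohort, n_perm=500, seed=13)
        for comp in COMPARTMENTS:
            pvals = table[table.compartment == comp].p_value.to_numpy()
            hits = int((pvals <= 0.1).sum())
            lo, hi = binom.ppf([0.005, 0.995], len(pvals), 0.1)
            assert lo <= hits <= hi

    def test_seed_stability_of_log_p(self, rng):
        """Different permutation streams agree up to Monte-Carlo noise."""
        import pandas as pd

        n, n_genes = 80, 60
        p = rng.beta(5, 3, n)
        resp = np.arange(n) < 40
        shift = np.linspace(0, 1.2, n_genes)[:, None] * resp[None, :]
        E = 6.0 * p + (3.0 + shift) * (1 - p) + rng.normal(0, 0.3, (n_genes, n))
        samples = [f"s{i}" for i in range(n)]
        cohort = CohortData(
            cohort_id="c",
            expression=pd.DataFrame(E, index=[f"g{i:03d}" for i in range(n_genes)], columns=samples),
            purity=pd.Series(p, index=samples),
            response=pd.Series(np.where(resp, io.RESPONDER, io.NONRESPONDER), index=samples),
        )
        t1 = io.cohort_de(cohort, n_perm=2000, seed=1)
        t2 = io.cohort_de(cohort, n_perm=2000, seed=2)
        s1 = t1[t1.compartment == io.STROMA].set_index("gene_id").p_value
        s2 = t2[t2.compartment == io.STROMA].set_index("gene_id").p_value
        r = np.corrcoef(-np.log10(s1), -np.log10(s2))[0, 1]
        assert r > 0.95


class TestMonotonicity:
    def test_larger_planted_effect_never_raises_mean_p(self, rng):
        """Monte-Carlo mean stroma p-value is non-increasing in the planted
        stromal effect size."""
        mean_p = []
        for effect in (0.0, 1.0, 2.0):
            ps = []
            for rep in range(8):
                e, p, labels = _mini_cohort(rng, n=40, stroma_shift=effect, sigma=0.4)
                res = {r.compartment: r for r in io.permutation_test(e, p, labels, n_perm=300, seed=rep)}
                ps.append(res[io.STROMA].p_value)
            mean_p.append(np.mean(ps))
        assert mean_p[0] >= mean_p[1] >= mean_p[2]


class TestCompartmentSpecificity:
    def test_effects_land_in_their_own_compartment(self, rng):
        """Cancer-only effects are significant in the cancer compartment and
        calibrated-null in the stroma compartment, and vice versa, for data
        generated additively on the model scale at moderate noise."""
        import pandas as pd

        n = 150
        p = rng.beta(5, 3, n)
        resp = np.arange(n) < 75
        rows, kinds = [], []
        for _ in range(10):  # cancer-only genes
            rows.append((6.0 + 1.0 * resp) * p + 3.0 * (1 - p) + rng.normal(0, 0.3, n))
            kinds.append("cancer")
        for _ in range(10):  # stroma-only genes
            rows.append(6.0 * p + (3.0 + 1.0 * resp) * (1 - p) + rng.normal(0, 0.3, n))
            kinds.append("stroma")
        samples = [f"s{i}" for i in range(n)]
        cohort = CohortData(
            cohort_id="spec",
            expression=pd.DataFrame(np.array(rows), index=[f"g{i:02d}" for i in range(20)], columns=samples),
            purity=pd.Series(p, index=samples),
            response=pd.Series(np.where(resp, io.RESPONDER, io.NONRESPONDER), index=samples),
        )
        table = io.cohort_de(cohort, n_perm=1000, seed=21)
        piv = table.pivot(index="gene_id", columns="compartment", values="p_value")
        kinds = pd.Series(kinds, index=[f"g{i:02d}" for i in range(20)])
        assert (piv.loc[kinds == "cancer", io.CANCER] <= 0.01).all()
        assert (piv.loc[kinds == "stroma", io.STROMA] <= 0.01).all()
        # off-target compartment stays unremarkable
        assert (piv.loc[kinds == "cancer", io.STROMA] > 0.05).mean() >= 0.8
        assert (piv.loc[kinds == "stroma", io.CANCER] > 0.05).mean() >= 0.8
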