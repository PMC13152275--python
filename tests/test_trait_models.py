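"""Likelihoods, model fits, information criteria, and phylogenetic signal."""

import math

import numpy as np
import pytest
from scipy import stats

from ovoflux.phylo import PhyloCovariance, parse_newick, transform_covariance, vcv_matrix
from ovoflux.synthetic import simulate_tree
from ovoflux.trait_models import (
    aicc,
    akaike_weights,
    fit_model,
    mvn_loglik,
    phylo_signal_lambda,
)

# A fixed 12-tip dataset whose Pagel's-lambda fit was checked against an
# independent reference implementation (phytools::phylosig); the boundary
# optimum and its log-likelihood are frozen below.
ORACLE_12_NWK = (
    "(((sp_001:0.366739356971,sp_002:0.366739356971):0.252070882114,"
    "(((((sp_011:0.00406348474119,sp_012:0.00406348474119):0.0355034873976,"
    "sp_010:0.0395669721388):0.134754257501,sp_005:0.17432122964):0.00359205056577,"
    "sp_004:0.177913280206):0.0745169088153,(sp_006:0.132837903462,"
    "sp_007:0.132837903462):0.119592285559):0.366380050064):0.381189760915,"
    "((sp_008:0.0944677206532,sp_009:0.0944677206532):0.250090799289,"
    "sp_003:0.344558519942):0.655441480058);"
)
ORACLE_12_X = {
    "sp_001": 1.2442295067, "sp_002": 1.7201144925, "sp_003": 0.4144706186,
    "sp_004": 0.2862810989, "sp_005": -0.9431211422, "sp_006": 1.1556821845,
    "sp_007": 0.6185843827, "sp_008": 0.9588864397, "sp_009": 0.2169055879,
    "sp_010": 1.3587267845, "sp_011": 1.404733858, "sp_012": 0.8095074605,
}
ORACLE_12_LOGL = -12.5470192440  # at the boundary optimum lambda = 0

ORACLE_20_NWK = (
    "(((((sp_019:0.0729337546549,sp_020:0.0729337546549):0.4430956682,"
    "sp_004:0.516029422855):0.303635097114,sp_001:0.819664519968):0.137994569588,"
    "((((sp_006:0.412701549386,sp_007:0.412701549386):0.0374818004842,"
    "((((sp_017:0.0985576118457,sp_018:0.0985576118457):0.0808000026683,"
    "sp_012:0.179357614514):0.0129979730648,(sp_013:0.16655045442,"
    "sp_014:0.16655045442):0.0258051331591):0.0457699319581,"
    "sp_011:0.238125519537):0.212057830333):0.081227919475,"
    "sp_003:0.531411269345):0.284030358014,((sp_009:0.321741510501,"
    "sp_010:0.321741510501):0.161840469191,sp_005:0.483581979692):0.331859647667)"
    ":0.142217462198):0.0423409104433,(((sp_015:0.146738957447,"
    "sp_016:0.146738957447):0.216656093826,sp_008:0.363395051273):0.172405781291,"
    "sp_002:0.535800832564):0.464199167436);"
)
ORACLE_20_X = {
    "sp_001": -0.0096545247, "sp_002": 1.4794700322, "sp_003": 1.0480175120,
    "sp_004": 1.0412457371, "sp_005": 2.4263883773, "sp_006": -1.0437894426,
    "sp_007": -0.7619059474, "sp_008": -1.2856106530, "sp_009": 0.6719110305,
    "sp_010": 1.9638806181, "sp_011": -0.1089874838, "sp_012": 0.4716072794,
    "sp_013": -1.9603879224, "sp_014": -0.3268990312, "sp_015": -1.3127199073,
    "sp_016": 1.2120192127, "sp_017": 0.5357692118, "sp_018": 0.8185410738,
    "sp_019": 0.2982501361, "sp_020": 0.9784475286,
}
ORACLE_20_LAMBDA = 0.0687484957
ORACLE_20_LOGL = -30.7585759492
ORACLE_20_LOGL0 = -30.7640162347


class TestMvnLoglik:
    def test_iid_standard_normal(self, cherry):
        C = vcv_matrix(cherry)  # identity
        ll = mvn_loglik({"A": 0.0, "B": 0.0}, C, sigma2=1.0, z0=0.0)
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_matches_dense_density_oracle(self, three_tip):
        C = vcv_matrix(three_tip)
        x = {"A": 0.3, "B": -0.5, "C": 1.1}
        s2, z0 = 0.7, 0.2
        ll = mvn_loglik(x, C, sigma2=s2, z0=z0)
        xv = np.array([x[lab] for lab in C.labels])
        ref = stats.multivariate_normal(mean=np.full(3, z0),
                                        cov=s2 * C.matrix).logpdf(xv)
        assert ll == pytest.approx(ref, abs=1e-8)

    def test_scaling_identity(self, three_tip):
        C = vcv_matrix(three_tip)
        x = {"A": 0.3, "B": -0.5, "C": 1.1}
        s = 1.7
        lhs = mvn_loglik(x, C, sigma2=s**2, z0=0.0)
        rhs = mvn_loglik({k: v / s for k, v in x.items()}, C, 1.0, 0.0) - 3 * math.log(s)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_rejects_nonpositive_sigma2(self, three_tip):
        with pytest.raises(ValueError):
            mvn_loglik({"A": 0, "B": 0, "C": 0}, vcv_matrix(three_tip), 0.0, 0.0)


class TestAicc:
    def test_closed_form(self):
        assert aicc(0.0, 2, 108) == pytest.approx(4 + 12 / 105)

    def test_k_zero_equals_aic(self):
        assert aicc(-1.0, 0, 10) == pytest.approx(2.0)

    def test_large_n_limit(self):
        assert abs(aicc(0.0, 3, 10**5) - 6.0) < 1e-3

    def test_small_n_domain_error(self):
        with pytest.raises(ValueError):
            aicc(0.0, 3, 4)


class TestAkaikeWeights:
    def test_symmetry(self):
        assert np.allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])

    def test_logistic_pair(self):
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-10)

    @pytest.mark.parametrize("vals", [[3.1], [5, 1, 9, 2.2], list(range(10))])
    def test_normalization_and_ordering(self, vals):
        w = akaike_weights(vals)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(w) == np.argmin(vals)


class TestFitModel:
    def test_lambda_matches_reference_boundary(self):
        t = parse_newick(ORACLE_12_NWK)
        fit = fit_model(t, ORACLE_12_X, "lambda")
        assert fit.shape == pytest.approx(0.0, abs=1e-3)
        assert fit.loglik == pytest.approx(ORACLE_12_LOGL, abs=1e-6)

    def test_lambda_matches_reference_interior(self):
        t = parse_newick(ORACLE_20_NWK)
        fit = fit_model(t, ORACLE_20_X, "lambda")
        assert fit.shape == pytest.approx(ORACLE_20_LAMBDA, abs=1e-4)
        assert fit.loglik == pytest.approx(ORACLE_20_LOGL, abs=1e-6)

    def test_lambda_nests_bm(self, tree20):
        rng = np.random.default_rng(0)
        x = dict(zip(tree20.tip_labels, rng.standard_normal(20)))
        bm = fit_model(tree20, x, "BM")
        lam = fit_model(tree20, x, "lambda")
        assert lam.loglik >= bm.loglik - 1e-8
        assert bm.k == 2 and lam.k == 3
        assert lam.aicc >= lam.aic

    def test_ou_small_alpha_equals_bm_loglik(self, tree20):
        rng = np.random.default_rng(1)
        C = vcv_matrix(tree20)
        L = np.linalg.cholesky(C.matrix + 1e-12 * np.eye(20))
        x = dict(zip(C.labels, L @ rng.standard_normal(20)))
        bm = fit_model(tree20, x, "BM")
        from ovoflux.trait_models import _align, _profile_loglik
        Ct = transform_covariance(
            PhyloCovariance(C.matrix / tree20.height, C.labels), "OU", {"alpha": 1e-6})
        ll, _, _ = _profile_loglik(_align(x, Ct), Ct.matrix)
        assert ll == pytest.approx(bm.loglik, abs=1e-3)

    def test_deterministic_refits(self, tree20):
        rng = np.random.default_rng(2)
        x = dict(zip(tree20.tip_labels, rng.standard_normal(20)))
        f1 = fit_model(tree20, x, "OU")
        f2 = fit_model(tree20, x, "OU")
        assert f1.shape == pytest.approx(f2.shape, abs=1e-8)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_needs_three_tips(self, cherry):
        with pytest.raises(ValueError):
            fit_model(cherry, {"A": 0.0, "B": 1.0}, "BM")

    def test_ou_model_selection_sanity(self, chol100):
        """Across replicates generated under strong OU, OU wins AICc in
        the majority of replicates."""
        C, _ = chol100
        Cou = transform_covariance(C, "OU", {"alpha": 2.0})
        L = np.linalg.cholesky(Cou.matrix + 1e-12 * np.eye(C.n))
        rng = np.random.default_rng(3)
        wins = 0
        nrep = 30
        for _ in range(nrep):
            x = dict(zip(C.labels, L @ rng.standard_normal(C.n)))
            fits = {m: fit_model(None, x, m, C_bm=C) for m in ("BM", "lambda", "OU", "EB")}
            best = min(fits, key=lambda m: fits[m].aicc)
            wins += best == "OU"
        assert wins > nrep / 2


class TestPhyloSignal:
    def test_star_tree_flagged_degenerate(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        with pytest.warns(UserWarning, match="unidentifiable"):
            sig = phylo_signal_lambda(t, {"A": 0.1, "B": 0.4, "C": -0.2, "D": 0.9})
        assert sig.degenerate

    def test_interior_case_matches_reference(self):
        t = parse_newick(ORACLE_20_NWK)
        sig = phylo_signal_lambda(t, ORACLE_20_X)
        assert sig.loglik0 == pytest.approx(ORACLE_20_LOGL0, abs=1e-6)
        expected_lrt = 2 * (ORACLE_20_LOGL - ORACLE_20_LOGL0)
        assert sig.lrt == pytest.approx(expected_lrt, abs=1e-4)

    def test_bm_recovery_mean_lambda_near_one(self, chol100):
        C, L = chol100
        rng = np.random.default_rng(4)
        lams = []
        for _ in range(40):
            x = dict(zip(C.labels, L @ rng.standard_normal(C.n)))
            lams.append(phylo_signal_lambda_fast(C, x))
        assert abs(np.mean(lams) - 1.0) < 0.1


def phylo_signal_lambda_fast(C, x):
    fit = fit_model(None, x, "lambda", C_bm=C)
    return fit.shape
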