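"""Sparse multinomial logistic regression with automatic relevance determination.

The decoder is a softmax (multinomial logistic) classifier with one weight
vector per class and an independent zero-mean Gaussian prior on every weight,
whose per-weight precision ``alpha`` is re-estimated from the data
(automatic relevance determination, ARD). Training alternates:

1. **MAP step** — maximize the multinomial log-likelihood plus the Gaussian
   log-prior over the currently active weights (quasi-Newton, warm-started).
2. **ARD step** — update each precision from the Laplace (Gaussian)
   approximation of the posterior, using the diagonal of the full posterior
   covariance. The default "mackay" rule re-estimates retained precisions by
   effective degrees of freedom (``alpha_i <- gamma_i / w_i^2`` with
   ``gamma_i = 1 - alpha_i * var_ii``) and decides removal by the per-weight
   evidence test: when the weight's optimum of the approximate marginal
   likelihood is an infinite precision (quality factor ``q_i^2`` at most the
   sparsity factor ``s_i``), its precision is set to infinity. Two pure
   alternatives are available: "evidence" (precision set to its per-weight
   evidence optimum ``s_i^2 / (q_i^2 - s_i)``; greedier, can discard
   redundant informative features once the fit nears separation) and
   "variational" (fixed point ``alpha_i <- 1 / (w_i^2 + var_ii)``; very slow
   to prune).

A weight whose precision exceeds ``prune_threshold`` is pruned: set to
exactly zero and removed from the active set for good. Irrelevant features
therefore leave the model entirely, which is what makes the classifier
usable when the feature dimension (e.g. 4560 site pairs) exceeds the sample
count. The bias is never pruned and its precision is held at a small fixed
value.

The estimator follows the scikit-learn API (``fit`` / ``predict`` /
``predict_proba``, ``get_params`` / ``set_params``) so it composes with
sklearn model selection; ``cross_validate`` adds the label-stratified
cross-validation harness used by the decoding experiments, reporting
per-fold percent accuracies and the surviving (non-zero-weight) features.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold


class SparseLogisticRegression(ClassifierMixin, BaseEstimator):
    """ARD-sparse softmax classifier.

    Parameters
    ----------
    alpha_init : float or None
        Initial per-weight prior precision. ``None`` (default) scales it
        with the feature count (``max(1, n_features / 4)``): starting from a
        deliberately strong prior approximates the empty-model start of
        constructive relevance determination, so the first evidence test
        ranks features by marginal signal instead of evaluating them inside
        an overfitted joint fit.
    prune_threshold : float
        A weight is pruned (fixed at exactly zero) once its precision
        exceeds this value. ``np.inf`` disables pruning.
    max_iter : int
        Maximum number of MAP/ARD alternations.
    tol : float
        Convergence tolerance on the largest absolute weight change.
    ard : bool
        If False, precisions stay at ``alpha_init`` (plain L2-penalized
        multinomial logistic regression).
    ard_rule : {"evidence", "mackay", "variational"}
        Precision update rule (see module docstring).
    standardize : bool
        Z-score features with training statistics before fitting. Reported
        ``coef_`` / ``intercept_`` are always on the original feature scale.
    bias_alpha : float
        Fixed prior precision of the (never pruned) bias weights.

    Attributes
    ----------
    classes_ : ndarray of shape (n_classes,)
    coef_ : ndarray of shape (n_classes, n_features)
        Weight vectors; pruned entries are exactly zero.
    intercept_ : ndarray of shape (n_classes,)
    alpha_ : ndarray of shape (n_classes, n_features)
        Final precisions (on the standardized scale when standardizing).
    active_mask_ : bool ndarray of shape (n_classes, n_features)
        False where the weight was pruned.
    n_iter_ : int
    converged_ : bool
    n_active_history_ : list[int]
        Active-weight count after every iteration (non-increasing).
    """

    def __init__(
        self,
        alpha_init: float | None = None,
        prune_threshold: float = 1e8,
        max_iter: int = 500,
        tol: float = 1e-6,
        ard: bool = True,
        ard_rule: str = "mackay",
        standardize: bool = True,
        bias_alpha: float = 1e-2,
        inner_max_iter: int = 100,
        inner_tol: float = 1e-10,
        inner_gtol: float = 1e-5,
    ) -> None:
        self.alpha_init = alpha_init
        self.prune_threshold = prune_threshold
        self.max_iter = max_iter
        self.tol = tol
        self.ard = ard
        self.ard_rule = ard_rule
        self.standardize = standardize
        self.bias_alpha = bias_alpha
        self.inner_max_iter = inner_max_iter
        self.inner_tol = inner_tol
        self.inner_gtol = inner_gtol

    # -- internals ---------------------------------------------------------

    def _map_step(self, phi, y_onehot, w, alpha, active, polish=False):
        """MAP estimate of the active weights given the precisions.

        Intermediate solves use a loose gradient tolerance (the precision
        re-estimates only need reasonable weights); the final ``polish``
        solve is tight.
        """
        k, d = w.shape
        idx = np.flatnonzero(active.ravel())
        alpha_eff = np.where(active, alpha, 0.0)  # pruned weights are pinned at 0
        # precondition by the estimated diagonal curvature (prior precision
        # plus the softmax curvature bound 1/4 sum_n phi_ni^2) so the
        # per-direction curvature spread stays modest
        curv = alpha + 0.25 * np.square(phi).sum(axis=0)[None, :]
        scale = 1.0 / np.sqrt(curv.ravel()[idx])

        def objective(v_flat):
            full = np.zeros(k * d)
            full[idx] = v_flat * scale
            wm = full.reshape(k, d)
            scores = phi @ wm.T
            mx = scores.max(axis=1, keepdims=True)
            es = np.exp(scores - mx)
            z = es.sum(axis=1, keepdims=True)
            log_z = mx + np.log(z)
            nll = float(log_z.sum() - np.sum(scores * y_onehot))
            prior = 0.5 * float(np.sum(alpha_eff * wm * wm))
            grad = (es / z - y_onehot).T @ phi + alpha_eff * wm
            return nll + prior, grad.ravel()[idx] * scale

        res = optimize.minimize(
            objective,
            w.ravel()[idx] / scale,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": 1000 if polish else self.inner_max_iter,
                "ftol": 1e-14 if polish else self.inner_tol,
                "gtol": 1e-9 if polish else self.inner_gtol,
            },
        )
        out = np.zeros(k * d)
        out[idx] = res.x * scale
        return out.reshape(k, d)

    @staticmethod
    def _posterior_stats(phi, y_onehot, w, alpha, active):
        """Laplace-posterior statistics of the active weights.

        Returns ``(var, mu, s_fac)``: the diagonal of the full posterior
        covariance ``Sigma = H^-1`` (multinomial Hessian
        ``H = Psi^T B Psi + A`` with ``Psi = I_K (x) Phi`` and softmax weight
        blocks ``B[(c,n),(l,n)] = p_nc (delta_cl - p_nl)``), the linearized
        posterior mean ``mu = Sigma Psi^T u`` built from the working residual
        ``u = B Psi w + (y - p)``, and the per-weight sparsity statistic
        ``S_i = phi_i^T C^-1 phi_i`` (feature included). When the active
        weight count is small the Hessian is inverted directly; otherwise
        everything is computed in sample space through the push-through
        identity, which only needs an (n*K)-sized solve.
        """
        n = phi.shape[0]
        k = w.shape[0]
        scores = phi @ w.T
        p_raw = softmax(scores, axis=1)
        # floor the curvature weights so near-separable fits keep a usable
        # Laplace approximation (standard IRLS safeguard)
        p = np.clip(p_raw, 0.01, 0.99)
        var = np.zeros_like(alpha)
        mu = np.zeros_like(alpha)
        s_fac = np.zeros_like(alpha)
        acts = [np.flatnonzero(active[c]) for c in range(k)]
        d_tot = sum(len(a) for a in acts)
        if d_tot == 0:
            return var, mu, s_fac
        # working residual u = B Psi w + (y - p), per class block
        v = scores  # Psi w stacked per class
        pv = np.sum(p * v, axis=1)
        u = [p[:, c] * (v[:, c] - pv) + (y_onehot[:, c] - p_raw[:, c]) for c in range(k)]
        if d_tot <= n * k:
            # weight-space inversion of the exact (active) Hessian
            offs = np.cumsum([0] + [len(a) for a in acts])
            h = np.zeros((d_tot, d_tot))
            b_vec = np.zeros(d_tot)
            for c in range(k):
                pc = p[:, c]
                phc = phi[:, acts[c]]
                b_vec[offs[c]:offs[c + 1]] = phc.T @ u[c]
                for l in range(c, k):
                    r = pc * ((1.0 if c == l else 0.0) - p[:, l])
                    blk = (phc * r[:, None]).T @ phi[:, acts[l]]
                    h[offs[c]:offs[c + 1], offs[l]:offs[l + 1]] = blk
                    if l != c:
                        h[offs[l]:offs[l + 1], offs[c]:offs[c + 1]] = blk.T
                h[offs[c]:offs[c + 1], offs[c]:offs[c + 1]] += np.diag(alpha[c, acts[c]])
            sigma = np.linalg.inv(h)
            mu_all = sigma @ b_vec
            cov_diag = np.diag(sigma)
            for c in range(k):
                al = alpha[c, acts[c]]
                var[c, acts[c]] = cov_diag[offs[c]:offs[c + 1]]
                mu[c, acts[c]] = mu_all[offs[c]:offs[c + 1]]
                s_fac[c, acts[c]] = al - al * al * cov_diag[offs[c]:offs[c + 1]]
        else:
            # sample-space route: M = Psi A^-1 Psi^T is block diagonal
            m = np.zeros((n * k, n * k))
            for c in range(k):
                sc = phi[:, acts[c]] / np.sqrt(alpha[c, acts[c]])
                m[c * n:(c + 1) * n, c * n:(c + 1) * n] = sc @ sc.T
            bmat = np.zeros((n * k, n * k))
            for c in range(k):
                for l in range(k):
                    np.fill_diagonal(
                        bmat[c * n:(c + 1) * n, l * n:(l + 1) * n],
                        p[:, c] * ((1.0 if c == l else 0.0) - p[:, l]),
                    )
            lhs = np.eye(n * k) + bmat @ m
            g = np.linalg.solve(lhs, bmat)
            u_stack = np.concatenate(u)
            t2 = np.linalg.solve(lhs, bmat @ (m @ u_stack))
            for c in range(k):
                gcc = g[c * n:(c + 1) * n, c * n:(c + 1) * n]
                phc = phi[:, acts[c]]
                quad = np.einsum("nd,nd->d", phc, gcc @ phc)
                al = alpha[c, acts[c]]
                var[c, acts[c]] = 1.0 / al - quad / (al * al)
                s_fac[c, acts[c]] = quad
                resid = u[c] - t2[c * n:(c + 1) * n]
                mu[c, acts[c]] = (phc.T @ resid) / al
        np.clip(var, 1e-12, None, out=var)
        return var, mu, s_fac

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if self.ard_rule not in ("evidence", "mackay", "variational"):
            raise ValueError(f"unknown ard_rule {self.ard_rule!r}")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        n, d = X.shape

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
            xs = (X - self.mean_) / self.scale_
        else:
            self.mean_ = np.zeros(d)
            self.scale_ = np.ones(d)
            xs = X
        phi = np.hstack([xs, np.ones((n, 1))])
        y_onehot = np.zeros((n, n_classes))
        y_onehot[np.arange(n), y_idx] = 1.0

        alpha0 = self.alpha_init if self.alpha_init is not None else max(1.0, d / 4.0)
        w = np.zeros((n_classes, d + 1))
        alpha = np.full((n_classes, d + 1), float(alpha0))
        alpha[:, -1] = self.bias_alpha
        active = np.ones((n_classes, d + 1), dtype=bool)

        self.n_active_history_ = []
        self.converged_ = False
        it = 0
        for it in range(1, self.max_iter + 1):
            w_new = self._map_step(phi, y_onehot, w, alpha, active)
            delta = float(np.max(np.abs(w_new - w)))
            w = w_new
            if self.ard:
                var, mu, s_all = self._posterior_stats(phi, y_onehot, w, alpha, active)
                feat = active.copy()
                feat[:, -1] = False  # bias precision stays fixed
                with np.errstate(divide="ignore", invalid="ignore"):
                    if self.ard_rule == "evidence":
                        # per-weight optimum of the marginal likelihood via the
                        # feature-excluded sparsity/quality factors
                        # s = a S / (a - S), q = a Q / (a - S) with Q = a mu;
                        # the retain test q^2 > s and the optimum s^2/(q^2 - s)
                        # are evaluated in the cancellation-free combined form
                        # psi = Q^2 - S + S^2/a  (retain iff psi > 0,
                        # alpha <- S^2 / psi)
                        q_in = alpha * mu
                        psi = np.square(q_in) - s_all + np.square(s_all) / alpha
                        new_alpha = np.where(psi > 0, np.square(s_all) / psi, np.inf)
                    elif self.ard_rule == "mackay":
                        # effective-degrees re-estimation, with the evidence
                        # test deciding removal: a weight whose per-weight
                        # evidence optimum is infinite (psi <= 0) is pruned
                        gamma = 1.0 - alpha * var
                        new_alpha = gamma / np.square(w)
                        q_in = alpha * mu
                        psi = np.square(q_in) - s_all + np.square(s_all) / alpha
                        new_alpha = np.where(psi > 0, new_alpha, np.inf)
                    else:
                        new_alpha = 1.0 / (np.square(w) + var)
                new_alpha[np.isnan(new_alpha)] = np.inf
                new_alpha = np.maximum(new_alpha, 1e-12)
                alpha[feat] = new_alpha[feat]
                prune = feat & (alpha > self.prune_threshold)
                if prune.any():
                    delta = max(delta, float(np.max(np.abs(w[prune]))))
                    active[prune] = False
                    w[prune] = 0.0
                    alpha[prune] = np.inf
            self.n_active_history_.append(int(active[:, :-1].sum()))
            if delta < self.tol:
                self.converged_ = True
                break
        self.n_iter_ = it
        w = self._map_step(phi, y_onehot, w, alpha, active, polish=True)

        # report weights on the original feature scale
        self.coef_ = w[:, :-1] / self.scale_
        self.intercept_ = w[:, -1] - (w[:, :-1] * (self.mean_ / self.scale_)).sum(axis=1)
        self.alpha_ = alpha[:, :-1]
        self.active_mask_ = active[:, :-1]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        return X @ self.coef_.T + self.intercept_

    def predict_proba(self, X):
        """Softmax label probabilities; rows sum to one."""
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        """Label with the maximum probability; ties go to the lowest label index."""
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def selected_features(self) -> np.ndarray:
        """Indices of features with a non-zero weight in any class."""
        return np.flatnonzero(np.any(self.coef_ != 0.0, axis=0))


@dataclass
class DecodingResult:
    """Cross-validated decoding outcome.

    ``fold_accuracies`` are percentages; ``selected_features`` holds, per
    fold, the indices of features that survived pruning; ``confusion`` is a
    labels x labels count table accumulated over the test folds.
    """

    fold_accuracies: list[float]
    mean_accuracy: float
    selected_features: list[np.ndarray]
    confusion: np.ndarray
    classes: np.ndarray
    fold_sizes: list[int] = field(default_factory=list)


def cross_validate(
    X,
    y,
    n_folds: int = 10,
    seed: int = 0,
    estimator: SparseLogisticRegression | None = None,
    **slr_params,
) -> DecodingResult:
    """Label-stratified k-fold evaluation of the sparse decoder.

    Folds are stratified so every test fold holds an (almost) equal share of
    each label; with 100 samples per label and 10 folds each test fold has
    20 samples, 10 per label. Accuracy is the percentage of correctly
    labelled test samples per fold.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    base = estimator if estimator is not None else SparseLogisticRegression(**slr_params)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc, selected, fold_sizes = [], [], []
    for train, test in skf.split(X, y):
        model = clone(base).fit(X[train], y[train])
        pred = model.predict(X[test])
        fold_acc.append(100.0 * float(np.mean(pred == y[test])))
        selected.append(model.selected_features())
        fold_sizes.append(len(test))
        for t, p in zip(y[test], pred):
            confusion[cls_index[t], cls_index[p]] += 1
    return DecodingResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        selected_features=selected,
        confusion=confusion,
        classes=classes,
        fold_sizes=fold_sizes,
    )
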