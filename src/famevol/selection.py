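"""Codon site models (M0/M3/M7/M8) and branch-site model A.

The API follows the statsmodels convention: a model object is constructed
from data (codon alignment + tree), ``fit`` maximizes the likelihood and
returns a results object carrying estimates, per-site posteriors and a
``summary`` table.

Model structure
---------------
M0   one dN/dS ratio omega for all sites                  (1 free ratio param)
M3   discrete: K=3 classes (p0,p1,p2; omega0..2)          (5)
M7   omega ~ Beta(p, q) on (0,1), discretized             (2)
M8   mixture: p0 * Beta(p, q) + p1 * point mass omega>=1  (4)
A    branch-site: classes 0/1/2a/2b; foreground branches
     switch classes 2a/2b from (omega0, 1) to omega2 >= 1

The beta component is discretized into K equal-probability categories whose
omega values are the category conditional means.  Likelihoods come from the
shared pruning engine; optimization is bounded L-BFGS-B on transformed
parameters with seedable random multi-starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import betainc, expit, logit, softmax

from .alignment import CodonAlignment
from .gy94 import f3x4_codon_freqs, uniform_codon_freqs
from .likelihood import LikelihoodEngine
from .trees import Tree

SITE_MODEL_FREE_PARAMS = {"M0": 1, "M3": 5, "M7": 2, "M8": 4}

_LN = np.log


def discretize_beta(p: float, q: float, k: int = 10) -> np.ndarray:
    """Means of K equal-probability Beta(p, q) categories.

    Category boundaries are the j/K quantiles; the conditional mean over
    (x_lo, x_hi) is  (p/(p+q)) * (I(x_hi; p+1, q) - I(x_lo; p+1, q)) * K
    with I the regularized incomplete beta function.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be > 0")
    bounds = stats.beta.ppf(np.linspace(0, 1, k + 1), p, q)
    upper = betainc(p + 1, q, bounds)
    means = (p / (p + q)) * np.diff(upper) * k
    return np.clip(means, 1e-8, 1.0 - 1e-8)


@dataclass
class LrtResult:
    """2(lnL1 - lnL0) against a chi-square (or mixture) null."""

    two_delta_l: float
    df: int
    p_value: float
    flagged: bool = False  # negative statistic: optimizer artefact

    def __str__(self):  # pragma: no cover
        flag = "  [flagged: negative statistic]" if self.flagged else ""
        return (
            f"2*dlnL = {self.two_delta_l:.4g}, df = {self.df}, "
            f"p = {self.p_value:.4g}{flag}"
        )


def likelihood_ratio_test(
    lnl0: float, lnl1: float, df: int, mixture: bool = False
) -> LrtResult:
    """LRT of a null (lnl0) against a nesting alternative (lnl1).

    With ``mixture=True`` the null distribution is the 50:50 mix of a point
    mass at 0 and chi-square(df), the boundary convention for branch-site
    tests; the default is the conservative plain chi-square.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnl1 - lnl0)
    if stat < 0:
        return LrtResult(stat, df, 1.0, flagged=True)
    p = float(stats.chi2.sf(stat, df))
    if mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return LrtResult(stat, df, p)


def _chol_se(hess_inv_diag):
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.maximum(hess_inv_diag, 0.0))


# ---------------------------------------------------------------------------
# site models
# ---------------------------------------------------------------------------

_BOUND_LOGK = (_LN(0.02), _LN(99.0))
_BOUND_LOGS = (_LN(1e-3), _LN(1e3))
_BOUND_LOGW = (_LN(1e-5), _LN(99.0))
_BOUND_LOGIT = (-14.0, 14.0)
_BOUND_LOGBETA = (_LN(0.005), _LN(99.0))
_BOUND_LOGWS = (0.0, _LN(999.0))  # omega_s >= 1


class CodonSiteModel:
    """ML codon-substitution model with site-wise omega variation.

    Parameters
    ----------
    alignment : CodonAlignment
        Gap-aware codon alignment; no stop codons.
    tree : Tree
        Topology with branch lengths in expected substitutions/codon.
    codon_freqs : {"F3x4", "equal"} or array
        Equilibrium codon frequencies; F3x4 estimates them from the data.
    n_categories : int
        Beta discretization categories for M7/M8.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: Tree,
        codon_freqs="F3x4",
        n_categories: int = 10,
    ):
        self.alignment = alignment
        self.tree = tree
        self.n_categories = int(n_categories)
        if isinstance(codon_freqs, str):
            if codon_freqs == "F3x4":
                self.pi = f3x4_codon_freqs(alignment.sequences)
            elif codon_freqs == "equal":
                self.pi = uniform_codon_freqs()
            else:
                raise ValueError(f"unknown codon_freqs {codon_freqs!r}")
        else:
            self.pi = np.asarray(codon_freqs, dtype=float)
        self.engine = LikelihoodEngine(alignment, tree, self.pi)
        self._fit_cache: dict = {}

    # -- model-specific class structure ----------------------------------
    def _classes(self, model: str, x: np.ndarray):
        """(proportions, omegas, extras) from the transformed vector x[2:]."""
        y = x[2:]
        if model == "M0":
            return np.array([1.0]), np.array([np.exp(y[0])]), {}
        if model == "M3":
            props = softmax(np.array([y[0], y[1], 0.0]))
            omegas = np.exp(y[2:5])
            return props, omegas, {}
        if model == "M7":
            p, q = np.exp(y[0]), np.exp(y[1])
            k = self.n_categories
            return (
                np.full(k, 1.0 / k),
                discretize_beta(p, q, k),
                {"beta": (p, q)},
            )
        if model == "M8":
            p0 = expit(y[0])
            p, q = np.exp(y[1]), np.exp(y[2])
            ws = np.exp(y[3])
            k = self.n_categories
            props = np.concatenate([np.full(k, p0 / k), [1.0 - p0]])
            omegas = np.concatenate([discretize_beta(p, q, k), [ws]])
            return props, omegas, {"beta": (p, q), "p0": p0, "omega_s": ws}
        raise ValueError(f"unknown site model {model!r}")

    def _neg_loglike(self, model, x, fix_kappa, fix_scale):
        kappa = fix_kappa if fix_kappa is not None else np.exp(x[0])
        scale = fix_scale if fix_scale is not None else np.exp(x[1])
        props, omegas, _ = self._classes(model, x)
        try:
            lnl = self.engine.mixture_log_likelihood(kappa, scale, props, omegas)
        except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
            return 1e12
        return -lnl if np.isfinite(lnl) else 1e12

    def _starts(self, model: str, n_starts: int, rng: np.random.Generator):
        base = {
            "M0": [0.0, 0.0, _LN(0.3)],
            "M3": [0.0, 0.0, 0.0, 0.0, _LN(0.05), _LN(0.3), _LN(1.2)],
            "M7": [0.0, 0.0, _LN(0.8), _LN(2.0)],
            "M8": [0.0, 0.0, logit(0.9), _LN(0.8), _LN(2.0), _LN(2.0)],
        }[model]
        starts = [np.array(base)]
        # seed later models from earlier cached fits where nesting helps
        m0 = self._fit_cache.get(("M0",))
        if m0 is not None and model != "M0":
            x = starts[0].copy()
            x[0] = _LN(m0.kappa)
            x[1] = _LN(m0.scale)
            if model == "M3":
                w = max(m0.omegas[0], 1e-4)
                x[4:7] = [_LN(w * 0.5), _LN(w), _LN(min(w * 2, 90))]
            starts.insert(0, x)
        m7 = self._fit_cache.get(("M7",))
        if m7 is not None and model == "M8":
            p, q = m7.beta_params
            x = starts[0].copy()
            x[0], x[1] = _LN(m7.kappa), _LN(m7.scale)
            x[2:6] = [logit(0.995), _LN(p), _LN(q), _LN(1.0 + 1e-6)]
            starts.insert(0, x)
        n_dim = len(base)
        while len(starts) < n_starts:
            starts.append(rng.normal(scale=1.0, size=n_dim) + np.array(base))
        return starts[:n_starts]

    def _bounds(self, model: str):
        common = [_BOUND_LOGK, _BOUND_LOGS]
        tail = {
            "M0": [_BOUND_LOGW],
            "M3": [_BOUND_LOGIT] * 2 + [_BOUND_LOGW] * 3,
            "M7": [_BOUND_LOGBETA] * 2,
            "M8": [_BOUND_LOGIT] + [_BOUND_LOGBETA] * 2 + [_BOUND_LOGWS],
        }[model]
        return common + tail

    def fit(
        self,
        model: str = "M0",
        n_starts: int = 5,
        seed: int = 0,
        fix_kappa: float | None = None,
        fix_scale: float | None = None,
        reestimate_branch_lengths: bool = False,
        tol: float = 1e-8,
    ) -> "SiteModelFit":
        """Maximize lnL for *model*; returns a :class:`SiteModelFit`.

        By default the branch-length scale for M3/M7/M8 is fixed at the M0
        estimate (fit lazily and cached); pass
        ``reestimate_branch_lengths=True`` to free it.
        """
        if model not in SITE_MODEL_FREE_PARAMS:
            raise ValueError(f"unknown site model {model!r}")
        if (
            model != "M0"
            and fix_scale is None
            and not reestimate_branch_lengths
        ):
            m0 = self.fit("M0", n_starts=max(2, n_starts - 2), seed=seed)
            fix_scale = m0.scale
        rng = np.random.default_rng(seed)
        best = None
        for x0 in self._starts(model, n_starts, rng):
            res = optimize.minimize(
                lambda x: self._neg_loglike(model, x, fix_kappa, fix_scale),
                x0,
                method="L-BFGS-B",
                bounds=self._bounds(model),
                options={"maxiter": 500, "ftol": tol},
            )
            if best is None or res.fun < best.fun:
                best = res
        x = best.x
        kappa = fix_kappa if fix_kappa is not None else float(np.exp(x[0]))
        scale = fix_scale if fix_scale is not None else float(np.exp(x[1]))
        props, omegas, extras = self._classes(model, x)
        if model == "M3":  # sort classes by omega for reporting
            order = np.argsort(omegas)
            props, omegas = props[order], omegas[order]
        fit = SiteModelFit(
            model=self,
            model_name=model,
            kappa=kappa,
            scale=scale,
            proportions=np.asarray(props),
            omegas=np.asarray(omegas),
            beta_params=extras.get("beta"),
            p0=extras.get("p0"),
            omega_s=extras.get("omega_s"),
            lnL=-float(best.fun),
            n_free_params=SITE_MODEL_FREE_PARAMS[model],
            converged=bool(best.success),
        )
        cached = self._fit_cache.get((model,))
        if cached is None or fit.lnL > cached.lnL:
            self._fit_cache[(model,)] = fit
        return fit


@dataclass
class SiteModelFit:
    """Fitted site model: parameters, lnL, and empirical-Bayes machinery."""

    model: CodonSiteModel
    model_name: str
    kappa: float
    scale: float
    proportions: np.ndarray
    omegas: np.ndarray
    lnL: float
    n_free_params: int
    beta_params: tuple | None = None
    p0: float | None = None
    omega_s: float | None = None
    converged: bool = True

    def site_posteriors(self, method: str = "NEB") -> np.ndarray:
        """(n_sites, n_classes) posterior class memberships.

        NEB evaluates P(class k | site) ∝ p_k L_k(site) at the MLE; gridBEB
        averages the NEB posteriors over an 8-point grid of perturbed
        parameter values, weighted by each grid point's data likelihood — a
        cheap stand-in for full Bayes empirical Bayes integration.
        """
        if method == "NEB":
            return self._neb(self.kappa, self.proportions, self.omegas)
        if method == "gridBEB":
            return self._grid_beb()
        raise ValueError(f"unknown posterior method {method!r}")

    def _neb(self, kappa, props, omegas):
        logl = self.model.engine.site_log_likelihood_matrix(
            kappa, self.scale, omegas
        )
        logpost = logl + _LN(np.maximum(props, 1e-300))[:, None]
        logpost -= logpost.max(axis=0, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=0, keepdims=True)
        return post.T

    def _grid_beb(self, delta: float = 0.25):
        """Likelihood-weighted average of NEB over +-delta parameter shifts."""
        grids = []
        weights = []
        for dk in (-delta, delta):
            for dw in (-delta, delta):
                for dp in (-delta, delta):
                    kappa = self.kappa * (1 + dk)
                    omegas = self.omegas.copy()
                    omegas[-1] = max(omegas[-1] * (1 + dw), 1e-6)
                    props = self.proportions.copy()
                    props[-1] = np.clip(props[-1] * (1 + dp), 1e-6, 0.999)
                    props[:-1] *= (1 - props[-1]) / max(props[:-1].sum(), 1e-300)
                    lnl = self.model.engine.mixture_log_likelihood(
                        kappa, self.scale, props, omegas
                    )
                    grids.append(self._neb(kappa, props, omegas))
                    weights.append(lnl)
        w = np.exp(np.array(weights) - max(weights))
        w /= w.sum()
        return np.tensordot(w, np.array(grids), axes=1)

    def positive_site_classes(self) -> np.ndarray:
        return np.nonzero(self.omegas > 1.0)[0]

    def positive_sites(
        self, threshold: float = 0.95, method: str = "NEB"
    ) -> list[tuple[int, float]]:
        """Sites whose posterior mass on omega>1 classes exceeds *threshold*.

        Returns 1-based site indices with posteriors.  Models with no
        omega>1 class (M0 with omega<=1, M7) do not allow this test.
        """
        classes = self.positive_site_classes()
        if classes.size == 0:
            raise ValueError(
                f"{self.model_name}: positive-site inference not allowed "
                "(no omega > 1 class)"
            )
        post = self.site_posteriors(method)[:, classes].sum(axis=1)
        return [(i + 1, float(p)) for i, p in enumerate(post) if p > threshold]

    def summary(self) -> str:
        lines = [
            f"Codon site model {self.model_name}",
            "=" * 44,
            f"lnL          {self.lnL:14.4f}",
            f"kappa        {self.kappa:14.4f}",
            f"tree scale   {self.scale:14.4f}",
            f"free omega-distribution params: {self.n_free_params}",
        ]
        if self.beta_params:
            lines.append(
                f"beta(p, q)   ({self.beta_params[0]:.5f}, {self.beta_params[1]:.5f})"
            )
        if self.p0 is not None:
            lines.append(f"p0 (beta part) {self.p0:12.5f}")
            lines.append(f"omega_s      {self.omega_s:14.5f}")
        if self.model_name in ("M0", "M3"):
            for k, (p, w) in enumerate(zip(self.proportions, self.omegas)):
                lines.append(f"class {k}:  p = {p:.5f}  omega = {w:.5f}")
        return "\n".join(lines)


def fit_site_model(
    alignment: CodonAlignment, tree: Tree, model: str, **kwargs
) -> SiteModelFit:
    """Convenience wrapper: build a CodonSiteModel and fit *model*."""
    return CodonSiteModel(alignment, tree).fit(model, **kwargs)


# ---------------------------------------------------------------------------
# branch-site model A
# ---------------------------------------------------------------------------

class BranchSiteModel:
    """Branch-site model A on designated foreground branches.

    Four site classes: 0 (omega0 everywhere), 1 (neutral everywhere),
    2a (background omega0, foreground omega2), 2b (background 1,
    foreground omega2).  Class proportions are (p0, p1, p2*p0/(p0+p1),
    p2*p1/(p0+p1)).  The null hypothesis fixes omega2 = 1.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: Tree,
        foreground_branches=None,
        codon_freqs="F3x4",
    ):
        tree = tree.copy()
        if foreground_branches is not None:
            for node in tree.postorder():
                node.foreground = False
            tree.mark_foreground(foreground_branches)
        flags = [n.foreground for n in tree.postorder() if n is not tree.root]
        if not any(flags):
            raise ValueError("no foreground branches designated")
        if all(flags):
            raise ValueError("all branches foreground: no background to contrast")
        self.alignment = alignment
        self.tree = tree
        if isinstance(codon_freqs, str):
            self.pi = (
                f3x4_codon_freqs(alignment.sequences)
                if codon_freqs == "F3x4"
                else uniform_codon_freqs()
            )
        else:
            self.pi = np.asarray(codon_freqs, dtype=float)
        self.engine = LikelihoodEngine(alignment, tree, self.pi)

    @staticmethod
    def _expand(p0: float, p1: float, w0: float, w2: float):
        rest = max(1.0 - p0 - p1, 0.0)
        denom = max(p0 + p1, 1e-300)
        props = np.array([p0, p1, rest * p0 / denom, rest * p1 / denom])
        props /= props.sum()
        bg = np.array([w0, 1.0, w0, 1.0])
        fg = np.array([w0, 1.0, w2, w2])
        return props, bg, fg

    def _neg_loglike(self, x, null, fix_kappa, fix_scale):
        kappa = fix_kappa if fix_kappa is not None else np.exp(x[0])
        scale = fix_scale if fix_scale is not None else np.exp(x[1])
        y = x[2:]
        p = softmax(np.array([y[0], y[1], 0.0]))
        w0 = expit(y[2])
        w2 = 1.0 if null else float(np.exp(y[3]))
        props, bg, fg = self._expand(p[0], p[1], w0, w2)
        try:
            lnl = self.engine.mixture_log_likelihood(kappa, scale, props, bg, fg)
        except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
            return 1e12
        return -lnl if np.isfinite(lnl) else 1e12

    def fit(
        self,
        null: bool = False,
        n_starts: int = 3,
        seed: int = 0,
        fix_kappa: float | None = None,
        fix_scale: float | None = None,
    ) -> "BranchSiteFit":
        rng = np.random.default_rng(seed)
        base = np.array([_LN(2.0), 0.0, _LN(4.0), 0.0, logit(0.1), _LN(2.0)])
        starts = [base]
        while len(starts) < n_starts:
            starts.append(base + rng.normal(scale=0.8, size=base.size))
        bounds = [
            _BOUND_LOGK,
            _BOUND_LOGS,
            _BOUND_LOGIT,
            _BOUND_LOGIT,
            _BOUND_LOGIT,
            _BOUND_LOGWS,
        ]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                lambda x: self._neg_loglike(x, null, fix_kappa, fix_scale),
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        x = best.x
        kappa = fix_kappa if fix_kappa is not None else float(np.exp(x[0]))
        scale = fix_scale if fix_scale is not None else float(np.exp(x[1]))
        p = softmax(np.array([x[2], x[3], 0.0]))
        w0 = float(expit(x[4]))
        w2 = 1.0 if null else float(np.exp(x[5]))
        props, bg, fg = self._expand(p[0], p[1], w0, w2)
        return BranchSiteFit(
            model=self,
            null=null,
            kappa=kappa,
            scale=scale,
            proportions=props,
            omega0=w0,
            omega2=w2,
            lnL=-float(best.fun),
            converged=bool(best.success),
        )

    def fit_with_lrt(
        self, mixture: bool = False, **kwargs
    ) -> tuple["BranchSiteFit", "BranchSiteFit", LrtResult]:
        """Alternative and null fits plus the df=1 LRT."""
        alt = self.fit(null=False, **kwargs)
        null = self.fit(null=True, **kwargs)
        return alt, null, likelihood_ratio_test(null.lnL, alt.lnL, 1, mixture)


@dataclass
class BranchSiteFit:
    model: BranchSiteModel
    null: bool
    kappa: float
    scale: float
    proportions: np.ndarray  # classes 0, 1, 2a, 2b
    omega0: float
    omega2: float
    lnL: float
    converged: bool = True

    def site_posteriors(self) -> np.ndarray:
        """(n_sites, 4) NEB posteriors over classes 0/1/2a/2b."""
        _, bg, fg = BranchSiteModel._expand(
            self.proportions[0], self.proportions[1], self.omega0, self.omega2
        )
        logl = self.model.engine.site_log_likelihood_matrix(
            self.kappa, self.scale, bg, fg
        )
        logpost = logl + _LN(np.maximum(self.proportions, 1e-300))[:, None]
        logpost -= logpost.max(axis=0, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=0, keepdims=True)
        return post.T

    def positive_sites(self, threshold: float = 0.95) -> list[tuple[int, float]]:
        """Foreground positively selected sites: posterior on classes 2a+2b."""
        post = self.site_posteriors()[:, 2:].sum(axis=1)
        return [(i + 1, float(p)) for i, p in enumerate(post) if p > threshold]

    def summary(self) -> str:
        rows = zip(
            ("0", "1", "2a", "2b"),
            self.proportions,
            (self.omega0, 1.0, self.omega0, 1.0),
            (self.omega0, 1.0, self.omega2, self.omega2),
        )
        lines = [
            f"Branch-site model A ({'null, omega2=1' if self.null else 'alternative'})",
            "=" * 56,
            f"lnL        {self.lnL:14.4f}",
            f"kappa      {self.kappa:14.4f}",
            "class   proportion   background_w   foreground_w",
        ]
        for name, p, wb, wf in rows:
            lines.append(f"{name:>5} {p:12.5f} {wb:14.5f} {wf:14.5f}")
        return "\n".join(lines)


def fit_branch_site(
    alignment: CodonAlignment,
    tree: Tree,
    foreground_branches,
    **kwargs,
) -> tuple[BranchSiteFit, BranchSiteFit, LrtResult]:
    """Model A alternative + null fits and their LRT, in one call."""
    model = BranchSiteModel(alignment, tree, foreground_branches)
    return model.fit_with_lrt(**kwargs)
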