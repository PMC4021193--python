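"""Type-I and type-II functional divergence between paralogous clusters.

Type-I divergence (site-specific rate shift after duplication) follows the
Gu-style rate-correlation mixture: a fraction theta of sites draw
independent gamma-distributed evolutionary rates in the two clusters, the
remainder share one rate.  The observable per site is the Fitch-parsimony
minimum substitution count within each cluster's subtree; counts are
Poisson given the rate, so the marginals are negative-binomial-type closed
forms and theta is estimated by ML.

Type-II divergence (site-specific physicochemical shift) uses a moment
construction: among sites fixed (internally conserved) in both clusters,
the excess of radical between-cluster differences — consensus residues in
different physicochemical groups — over the radical rate expected from
within-cluster polymorphism.  The estimate may be negative and is reported
unclamped.

Per-site posteriors Qk feed critical-amino-acid-site (CAAS) calling at a
strict cutoff (default Qk > 0.95).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln, logit, logsumexp

from .alignment import Alignment, GAP_CHARS
from .trees import Tree

MIN_CLUSTER_SIZE = 4  # groups with fewer sequences cannot be analyzed

#: physicochemical residue grouping (charge / polarity / aromaticity);
#: a substitution across groups is "radical", within a group "conservative"
RESIDUE_GROUPS = {
    "aliphatic": "GAVLIPM",
    "aromatic": "FWY",
    "polar": "STCNQ",
    "acidic": "DE",
    "basic": "KRH",
}

_GROUP_OF = {aa: g for g, members in RESIDUE_GROUPS.items() for aa in members}


def residue_group(aa: str) -> str:
    try:
        return _GROUP_OF[aa.upper()]
    except KeyError:
        raise ValueError(f"no physicochemical group for residue {aa!r}")


def is_radical(a: str, b: str) -> bool:
    return residue_group(a) != residue_group(b)


# ---------------------------------------------------------------------------
# Fitch parsimony substitution counts
# ---------------------------------------------------------------------------

@dataclass
class SiteSubstitutionProfile:
    cluster_id: str
    counts: np.ndarray  # per-site minimum changes
    subtree_length: float

    @property
    def n_sites(self) -> int:
        return len(self.counts)


def fitch_counts(alignment: Alignment, tree: Tree) -> np.ndarray:
    """Per-site Fitch minimum-change counts on *tree* over all its leaves.

    Gap/unknown residues contribute the full residue alphabet (missing
    data) and therefore never force a change.
    """
    leaves = tree.leaf_names
    cols = {name: alignment[name] for name in leaves}
    n_sites = len(alignment)
    counts = np.zeros(n_sites, dtype=int)
    post = list(tree.postorder())
    full = frozenset("ACDEFGHIKLMNPQRSTVWY")
    for s in range(n_sites):
        sets: dict = {}
        changes = 0
        for node in post:
            if node.is_leaf:
                aa = cols[node.name][s]
                sets[node] = frozenset(aa) if aa not in GAP_CHARS and aa != "X" else full
                continue
            acc = None
            for child in node.children:
                cs = sets.pop(child)
                if acc is None:
                    acc = cs
                    continue
                inter = acc & cs
                if inter:
                    acc = inter
                else:
                    acc = acc | cs
                    changes += 1
            sets[node] = acc
        counts[s] = changes
    return counts


def parsimony_site_counts(
    alignment: Alignment, tree: Tree, cluster_leaves, cluster_id: str = ""
) -> SiteSubstitutionProfile:
    """Fitch counts restricted to one cluster's induced subtree."""
    cluster_leaves = list(cluster_leaves)
    if len(cluster_leaves) < 2:
        raise ValueError("cluster needs at least 2 leaves for parsimony counts")
    sub = tree.extract_subtree(cluster_leaves)
    counts = fitch_counts(alignment, sub)
    return SiteSubstitutionProfile(cluster_id, counts, sub.total_branch_length())


# ---------------------------------------------------------------------------
# results container shared by both divergence types
# ---------------------------------------------------------------------------

@dataclass
class DivergenceFit:
    """Fitted divergence coefficient with per-site posteriors."""

    cluster_a: str
    cluster_b: str
    kind: str  # "type1" | "type2"
    theta: float
    se: float
    qk: np.ndarray
    lrt_statistic: float | None = None
    p_value: float | None = None
    boundary: bool = False
    extras: dict = field(default_factory=dict)

    def caas(self, cutoff: float = 0.95) -> list[int]:
        return call_caas(self, cutoff)

    def summary(self) -> str:
        sig = ""
        if self.p_value is not None:
            sig = f"  LRT = {self.lrt_statistic:.3f}, p = {self.p_value:.3g}"
        return (
            f"{self.kind} divergence {self.cluster_a}/{self.cluster_b}: "
            f"theta = {self.theta:.3f} ± {self.se:.3f}{sig}; "
            f"CAAS(Qk>0.95): {len(self.caas())}"
        )


def call_caas(fit: DivergenceFit, cutoff: float = 0.95) -> list[int]:
    """1-based alignment columns with posterior Qk strictly above *cutoff*."""
    return [i + 1 for i, q in enumerate(fit.qk) if q > cutoff]


def intersect_caas(sites_a, sites_b) -> list[int]:
    """Sites called in both analyses (e.g. type-I ∩ type-II)."""
    if isinstance(sites_a, DivergenceFit):
        sites_a = sites_a.caas()
    if isinstance(sites_b, DivergenceFit):
        sites_b = sites_b.caas()
    return sorted(set(sites_a) & set(sites_b))


# ---------------------------------------------------------------------------
# type-I: rate-correlation mixture on parsimony counts
# ---------------------------------------------------------------------------

def _log_nb2(x, y, alpha, da, db):
    """log P(x, y) when one shared Gamma(alpha, rate alpha) rate drives both."""
    tot = alpha + da + db
    return (
        gammaln(alpha + x + y)
        - gammaln(alpha)
        - gammaln(x + 1)
        - gammaln(y + 1)
        + x * np.log(da)
        + y * np.log(db)
        + alpha * np.log(alpha)
        - (alpha + x + y) * np.log(tot)
    )


def _log_nb1(x, alpha, d):
    """log P(x) for a Poisson with independent Gamma(alpha, rate alpha) rate."""
    return (
        gammaln(alpha + x)
        - gammaln(alpha)
        - gammaln(x + 1)
        + x * np.log(d)
        + alpha * np.log(alpha)
        - (alpha + x) * np.log(alpha + d)
    )


class Type1Divergence:
    """ML model of site-specific rate shift between two count profiles."""

    def __init__(
        self,
        profile_a: SiteSubstitutionProfile,
        profile_b: SiteSubstitutionProfile,
        n_sequences: tuple[int, int] | None = None,
    ):
        if n_sequences is not None:
            for cid, n in zip((profile_a.cluster_id, profile_b.cluster_id), n_sequences):
                if n < MIN_CLUSTER_SIZE:
                    raise ValueError(
                        f"cluster {cid or '?'} has {n} sequences; groups with "
                        f"less than {MIN_CLUSTER_SIZE} sequences cannot be analyzed"
                    )
        if profile_a.n_sites != profile_b.n_sites:
            raise ValueError("profiles cover different numbers of sites")
        self.xa = np.asarray(profile_a.counts, dtype=float)
        self.xb = np.asarray(profile_b.counts, dtype=float)
        if self.xa.sum() == 0 and self.xb.sum() == 0:
            raise ValueError("all-zero counts in both clusters: theta inestimable")
        self.ids = (profile_a.cluster_id, profile_b.cluster_id)

    def _site_loglik_parts(self, alpha, da, db):
        shared = _log_nb2(self.xa, self.xb, alpha, da, db)
        indep = _log_nb1(self.xa, alpha, da) + _log_nb1(self.xb, alpha, db)
        return shared, indep

    def loglike(self, theta, alpha, da, db) -> float:
        shared, indep = self._site_loglik_parts(alpha, da, db)
        both = np.stack(
            [shared + np.log(max(1 - theta, 1e-300)),
             indep + np.log(max(theta, 1e-300))]
        )
        return float(logsumexp(both, axis=0).sum())

    def _neg(self, z, fix_theta=None):
        theta = fix_theta if fix_theta is not None else expit(z[0])
        alpha, da, db = np.exp(z[1:4])
        val = self.loglike(theta, alpha, da, db)
        return -val if np.isfinite(val) else 1e12

    def fit(self, n_starts: int = 10, seed: int = 0) -> DivergenceFit:
        rng = np.random.default_rng(seed)
        mean_a = max(self.xa.mean(), 1e-3)
        mean_b = max(self.xb.mean(), 1e-3)
        base = np.array([logit(0.3), math.log(1.0), math.log(mean_a), math.log(mean_b)])
        bounds = [(-12, 12), (math.log(1e-2), math.log(1e3))] + [
            (math.log(1e-4), math.log(1e4))
        ] * 2
        best = None
        for k in range(n_starts):
            z0 = base if k == 0 else base + rng.normal(scale=1.0, size=4)
            res = optimize.minimize(
                self._neg, z0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = float(expit(best.x[0]))
        alpha, da, db = np.exp(best.x[1:4])
        lnl1 = -best.fun

        # null: theta = 0
        null = None
        for k in range(max(3, n_starts // 3)):
            z0 = base[1:] if k == 0 else base[1:] + rng.normal(scale=1.0, size=3)
            res = optimize.minimize(
                lambda z: self._neg(np.concatenate([[0.0], z]), fix_theta=0.0),
                z0, method="L-BFGS-B", bounds=bounds[1:],
                options={"maxiter": 500},
            )
            if null is None or res.fun < null.fun:
                null = res
        lrt = max(0.0, 2.0 * (lnl1 - (-null.fun)))
        p = float(stats.chi2.sf(lrt, 1))

        # posterior Q_k and a curvature-based s.e. for theta
        shared, indep = self._site_loglik_parts(alpha, da, db)
        num = np.log(max(theta, 1e-300)) + indep
        den = logsumexp(
            np.stack([num, np.log(max(1 - theta, 1e-300)) + shared]), axis=0
        )
        qk = np.exp(num - den)
        se = self._theta_se(best.x)
        boundary = theta < 1e-4 or theta > 1 - 1e-4
        return DivergenceFit(
            cluster_a=self.ids[0],
            cluster_b=self.ids[1],
            kind="type1",
            theta=min(max(theta, 0.0), 1.0),
            se=se,
            qk=qk,
            lrt_statistic=lrt,
            p_value=p,
            boundary=boundary,
            extras={"alpha": float(alpha), "d_a": float(da), "d_b": float(db),
                    "lnL": float(lnl1)},
        )

    def _theta_se(self, z_hat, eps: float = 1e-4) -> float:
        """Delta-method s.e. of theta from the profile curvature in logit space."""
        def nll(t0):
            return self._neg(np.concatenate([[t0], z_hat[1:]]))

        t = z_hat[0]
        d2 = (nll(t + eps) - 2 * nll(t) + nll(t - eps)) / eps**2
        if d2 <= 0:
            return math.inf
        var_logit = 1.0 / d2
        theta = expit(t)
        return float(math.sqrt(var_logit) * theta * (1 - theta))


def fit_type1_divergence(
    profile_a: SiteSubstitutionProfile,
    profile_b: SiteSubstitutionProfile,
    **kwargs,
) -> DivergenceFit:
    return Type1Divergence(profile_a, profile_b).fit(**kwargs)


def type1_divergence_from_tree(
    alignment: Alignment,
    tree: Tree,
    leaves_a,
    leaves_b,
    cluster_ids: tuple[str, str] = ("A", "B"),
    **fit_kwargs,
) -> DivergenceFit:
    """Parsimony counts per cluster subtree, then the type-I mixture fit.

    Clusters with fewer than four sequences cannot be analyzed (the model
    has no power to separate rate classes) and raise a ValueError.
    """
    leaves_a, leaves_b = list(leaves_a), list(leaves_b)
    prof_a = parsimony_site_counts(alignment, tree, leaves_a, cluster_ids[0])
    prof_b = parsimony_site_counts(alignment, tree, leaves_b, cluster_ids[1])
    model = Type1Divergence(
        prof_a, prof_b, n_sequences=(len(leaves_a), len(leaves_b))
    )
    return model.fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# type-II: radical fixed differences vs within-cluster polymorphism
# ---------------------------------------------------------------------------

def _column_states(alignment: Alignment, names, site) -> list[str]:
    return [
        alignment[n][site]
        for n in names
        if alignment[n][site] not in GAP_CHARS and alignment[n][site] != "X"
    ]


class Type2Divergence:
    """Moment estimator of the physicochemical-shift fraction theta-II."""

    def __init__(
        self,
        alignment_a: Alignment,
        alignment_b: Alignment,
        cluster_ids: tuple[str, str] = ("A", "B"),
    ):
        for aln, cid in zip((alignment_a, alignment_b), cluster_ids):
            if aln.n_sequences < MIN_CLUSTER_SIZE:
                raise ValueError(
                    f"cluster {cid} has {aln.n_sequences} sequences; groups with "
                    f"less than {MIN_CLUSTER_SIZE} sequences cannot be analyzed"
                )
        if len(alignment_a) != len(alignment_b):
            raise ValueError("cluster alignments cover different sites")
        self.a = alignment_a
        self.b = alignment_b
        self.ids = cluster_ids

    def fit(self) -> DivergenceFit:
        n_sites = len(self.a)
        fixed_diff = np.zeros(n_sites, dtype=bool)   # both conserved, different
        radical = np.zeros(n_sites, dtype=bool)      # ... and group-changing
        n_fixed = 0
        poly_pairs = 0
        poly_radical = 0
        informative = 0
        for s in range(n_sites):
            col_a = _column_states(self.a, self.a.names, s)
            col_b = _column_states(self.b, self.b.names, s)
            if not col_a and not col_b:
                raise ValueError(f"site {s + 1}: entirely gapped in both clusters")
            if not col_a or not col_b:
                continue
            informative += 1
            cons_a, cnt_a = Counter(col_a).most_common(1)[0]
            cons_b, cnt_b = Counter(col_b).most_common(1)[0]
            # within-cluster polymorphism: variant residues vs the consensus
            for col, cons in ((col_a, cons_a), (col_b, cons_b)):
                for aa in col:
                    if aa != cons:
                        poly_pairs += 1
                        if is_radical(aa, cons):
                            poly_radical += 1
            if cnt_a == len(col_a) and cnt_b == len(col_b):
                n_fixed += 1
                if cons_a != cons_b:
                    fixed_diff[s] = True
                    if is_radical(cons_a, cons_b):
                        radical[s] = True
        n_diff = int(fixed_diff.sum())
        n_rad = int(radical.sum())
        # baseline: radical fraction among within-cluster (late-phase)
        # changes, regularized by one pseudo-observation at the uniform
        # residue-pair rate so tiny polymorphism samples cannot pin it to 0/1
        p_r = (poly_radical + _expected_radical_rate()) / (poly_pairs + 1)
        if n_diff == 0:
            theta = 0.0
            se = 0.0
        else:
            f = n_rad / n_diff
            theta = (f - p_r) / (1.0 - p_r)
            se = math.sqrt(max(f * (1 - f), 1e-12) / n_diff) / (1.0 - p_r)
        # posterior: divergent sites are radical fixed differences by model
        theta_c = min(max(theta, 0.0), 1.0)
        base_rate = (n_diff / n_fixed if n_fixed else 0.0) * p_r
        qk = np.zeros(n_sites)
        if theta_c > 0 or base_rate > 0:
            q_hit = (
                theta_c / (theta_c + (1 - theta_c) * base_rate)
                if (theta_c + (1 - theta_c) * base_rate) > 0
                else 0.0
            )
            qk[radical] = q_hit
        return DivergenceFit(
            cluster_a=self.ids[0],
            cluster_b=self.ids[1],
            kind="type2",
            theta=float(theta),
            se=float(se),
            qk=qk,
            extras={
                "n_fixed_sites": n_fixed,
                "n_fixed_differences": n_diff,
                "n_radical_differences": n_rad,
                "baseline_radical_rate": float(p_r),
                "n_informative_sites": informative,
            },
        )


def _expected_radical_rate() -> float:
    """Radical fraction over all unordered residue pairs (uniform baseline)."""
    aas = sorted(_GROUP_OF)
    pairs = [(a, b) for i, a in enumerate(aas) for b in aas[i + 1 :]]
    return sum(is_radical(a, b) for a, b in pairs) / len(pairs)


def fit_type2_divergence(
    alignment_a: Alignment,
    alignment_b: Alignment,
    cluster_ids: tuple[str, str] = ("A", "B"),
) -> DivergenceFit:
    return Type2Divergence(alignment_a, alignment_b, cluster_ids).fit()
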