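"""Penalized-likelihood divergence dating with fossil calibrations.

Given a rooted binary phylogram with branch lengths in expected
substitutions per site, node ages (Ma) and per-branch rates
(subst/site/Ma) are estimated by maximizing a Poisson branch-count
likelihood minus ``lambda`` times a rate-roughness penalty: squared
parent-child rate differences plus the variance of the rates of the
root's children. Calibrations are min/max age boxes on MRCAs; at least
one maximum (an upper bound somewhere) is required or the timescale is
unidentifiable. The smoothing parameter is chosen by leave-one-tip-out
cross-validation with a chi-square score, over a log-spaced grid
spanning 1e5 down to 1e-3.

Node ages are parameterized by proportional depths — each node's age is
its lower bound plus a fraction of the feasible window below its parent
— so the age ordering and all calibration boxes stay feasible under box
constraints; optimization is multi-start bounded quasi-Newton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize
from scipy.special import gammaln

_EPS_T = 1e-12
_X_FLOOR = 1e-9


@dataclass(frozen=True)
class CalibrationConstraint:
    """Min/max age (Ma) on the MRCA of a set of >= 2 tips."""

    tips: frozenset[str]
    min_age: float | None = None
    max_age: float | None = None

    def __post_init__(self) -> None:
        if len(self.tips) < 2:
            raise ValueError("a calibration needs >= 2 tip labels")
        if (
            self.min_age is not None
            and self.max_age is not None
            and self.min_age > self.max_age
        ):
            raise ValueError("calibration min age exceeds max age")


@dataclass
class ChronogramFit:
    """Result of one penalized-likelihood fit."""

    tree: dendropy.Tree  # chronogram: edge lengths are durations, node.age set
    node_ages: dict[int, float]  # internal-node preorder index -> age
    rates: np.ndarray  # per-branch rates, preorder branch order
    smoothing: float
    objective: float
    converged: bool
    n_sites: float
    objective_trace: list[list[float]] = field(default_factory=list)
    params: np.ndarray | None = None  # raw optimizer solution (warm starts)

    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    def tip_ages(self) -> dict[str, float]:
        return {lf.taxon.label: float(lf.age) for lf in self.tree.leaf_node_iter()}

    def mrca_age(self, tips: set[str]) -> float:
        taxa = [t for t in self.tree.taxon_namespace if t.label in tips]
        node = self.tree.mrca(taxa=taxa)
        return float(node.age)


class _PLProblem:
    """Flattened tree structure for the optimizer."""

    def __init__(
        self,
        tree: dendropy.Tree,
        constraints: list[CalibrationConstraint],
        n_sites: float,
        for_fitting: bool = True,
    ):
        self.n_sites = float(n_sites)
        tree.is_rooted = True  # dating requires a rooted tree; prevents
        # dendropy from derooting during MRCA lookups
        self.tree = tree
        nodes = list(tree.preorder_node_iter())
        self.nodes = nodes
        idx = {id(n): i for i, n in enumerate(nodes)}
        self.parent = np.array(
            [-1 if n.parent_node is None else idx[id(n.parent_node)] for n in nodes]
        )
        self.is_tip = np.array([n.is_leaf() for n in nodes])
        self.internal = np.where(~self.is_tip)[0]
        self.n_internal = len(self.internal)
        # branches: one per non-root node, in preorder node order
        self.branch_nodes = np.array([i for i in range(len(nodes)) if self.parent[i] >= 0])
        self.n_branches = len(self.branch_nodes)
        self.x = np.array(
            [
                max((nodes[i].edge.length or 0.0) * self.n_sites, _X_FLOOR)
                for i in self.branch_nodes
            ]
        )
        self._lgamma_x = gammaln(self.x + 1.0)
        # branch index of the parent edge (or -1 if the parent is the root)
        branch_of_node = {int(b): k for k, b in enumerate(self.branch_nodes)}
        self.parent_branch = np.array(
            [
                branch_of_node.get(int(self.parent[b]), -1)
                for b in self.branch_nodes
            ]
        )
        self.root_child_branches = np.array(
            [k for k, b in enumerate(self.branch_nodes) if self.parent[b] == 0]
        )
        if for_fitting:
            self._setup_bounds(constraints)
        else:
            self.lo = np.zeros(len(nodes))
            self.hi = np.full(len(nodes), np.inf)

    # -- calibration boxes --------------------------------------------------

    def _setup_bounds(self, constraints: list[CalibrationConstraint]) -> None:
        lo = np.zeros(len(self.nodes))
        hi = np.full(len(self.nodes), np.inf)
        tip_labels = {
            n.taxon.label: i for i, n in enumerate(self.nodes) if n.is_leaf()
        }
        for c in constraints:
            present = [t for t in c.tips if t in tip_labels]
            if len(present) < 2:
                continue
            node = self.tree.mrca(
                taxa=[t for t in self.tree.taxon_namespace if t.label in present]
            )
            i = self.nodes.index(node)
            if c.min_age is not None:
                lo[i] = max(lo[i], c.min_age)
            if c.max_age is not None:
                hi[i] = min(hi[i], c.max_age)
        # propagate: an ancestor is at least as old as any descendant's min,
        # a descendant no older than any ancestor's max
        for i in reversed(range(len(self.nodes))):  # postorder-ish over preorder
            p = self.parent[i]
            if p >= 0:
                lo[p] = max(lo[p], lo[i])
        for i in range(len(self.nodes)):
            p = self.parent[i]
            if p >= 0:
                hi[i] = min(hi[i], hi[p])
        bad = np.where(lo > hi + 1e-12)[0]
        if len(bad):
            names = [self._node_name(int(b)) for b in bad]
            raise ValueError(f"conflicting calibrations at node(s): {names}")
        if not np.isfinite(hi[0]):
            raise ValueError(
                "timescale unidentifiable: no maximum age bound anywhere"
            )
        self.lo, self.hi = lo, hi

    def _node_name(self, i: int) -> str:
        node = self.nodes[i]
        tips = sorted(lf.taxon.label for lf in node.leaf_iter())
        return "MRCA(" + ",".join(tips[:4]) + ("..." if len(tips) > 4 else "") + ")"

    # -- parameterization ---------------------------------------------------

    def ages_from_fractions(self, f: np.ndarray) -> np.ndarray:
        """Node ages from proportional depths (preorder fill)."""
        ages = np.zeros(len(self.nodes))
        fmap = dict(zip(self.internal, f))
        for i in range(len(self.nodes)):
            if self.is_tip[i]:
                ages[i] = 0.0
                continue
            p = self.parent[i]
            upper = self.hi[i] if p < 0 else min(self.hi[i], ages[p])
            lower = self.lo[i]
            window = max(upper - lower, 0.0)
            ages[i] = lower + fmap[i] * window
        return ages

    def objective(self, params: np.ndarray, lam: float) -> float:
        return self.objective_grad(params, lam)[0]

    def objective_grad(
        self, params: np.ndarray, lam: float
    ) -> tuple[float, np.ndarray]:
        """Objective -logL + lam*Phi and its analytic gradient.

        Gradients with respect to the proportional depths are obtained by
        forward accumulation through the age recursion: each node's age
        depends on its own fraction through the feasible window and on
        ancestral fractions through the parent age (unless the static
        upper bound binds).
        """
        n_nodes = len(self.nodes)
        nf = self.n_internal
        f = params[:nf]
        r = np.exp(params[nf:])
        fmap = dict(zip(self.internal, range(nf)))

        ages = np.zeros(n_nodes)
        D = np.zeros((n_nodes, nf))  # d age_i / d f_j
        for i in range(n_nodes):
            if self.is_tip[i]:
                continue
            j = fmap[i]
            p = self.parent[i]
            if p < 0:
                upper = self.hi[i]
                dupper = None
            elif ages[p] < self.hi[i]:
                upper = ages[p]
                dupper = D[p]
            else:
                upper = self.hi[i]
                dupper = None
            lower = self.lo[i]
            window = max(upper - lower, 0.0)
            ages[i] = lower + f[j] * window
            if window > 0.0:
                D[i, j] = window
                if dupper is not None:
                    D[i] += f[j] * dupper
                    D[i, j] = window  # own-fraction term overwritten above

        bn = self.branch_nodes
        pn = self.parent[bn]
        t = ages[pn] - ages[bn]
        clamped = t <= _EPS_T
        t = np.maximum(t, _EPS_T)
        mu = r * t * self.n_sites
        loglik = float(np.sum(self.x * np.log(mu) - mu - self._lgamma_x))

        # penalty on rates in units of their current mean, so it is
        # invariant to the age/rate scale ridge and the smoothing grid is
        # dimensionless
        nb = len(bn)
        rbar = r.mean()
        has_parent = self.parent_branch >= 0
        diffs = np.zeros(nb)
        diffs[has_parent] = r[has_parent] - r[self.parent_branch[has_parent]]
        pen_abs = float(np.sum(diffs * diffs))
        dpen_abs = 2.0 * diffs
        np.add.at(dpen_abs, self.parent_branch[has_parent], -2.0 * diffs[has_parent])
        rc = self.root_child_branches
        if len(rc) > 1:
            m = len(rc)
            mean_rc = r[rc].mean()
            pen_abs += float(np.sum((r[rc] - mean_rc) ** 2) / m)
            dpen_abs[rc] += 2.0 * (r[rc] - mean_rc) / m
        phi = pen_abs / (rbar * rbar)
        dphi = dpen_abs / (rbar * rbar) - 2.0 * pen_abs / (rbar**3 * nb)

        value = -loglik + lam * phi

        # gradient wrt log r: -(x - mu) + lam * dphi/dr * r
        grad_logr = -(self.x - mu) + lam * dphi * r
        # gradient wrt fractions, through branch durations
        dG_dt = -(self.x / t - r * self.n_sites)
        dG_dt[clamped] = 0.0
        grad_f = (D[pn] - D[bn]).T @ dG_dt
        return value, np.concatenate([grad_f, grad_logr])

    def init_rate(self) -> float:
        f0 = np.full(self.n_internal, 0.5)
        ages = self.ages_from_fractions(f0)
        t = np.maximum(
            ages[self.parent[self.branch_nodes]] - ages[self.branch_nodes], _EPS_T
        )
        return max(self.x.sum() / (self.n_sites * t.sum()), 1e-12)


def pl_objective_parts(
    tree: dendropy.Tree,
    ages: np.ndarray,
    rates: np.ndarray,
    n_sites: float,
    r_ref: float | None = None,
) -> tuple[float, float]:
    """Negative Poisson log-likelihood and rate-roughness penalty.

    ``ages`` is per preorder node (tips at 0), ``rates`` per preorder
    branch. A zero-duration branch carrying substitutions yields an
    infinite likelihood term (returned, not raised). The penalty sums
    squared parent-child rate differences plus the variance of the
    root's child rates, with rates measured in units of ``r_ref`` (by
    default the global rate implied by the inputs) so the smoothing
    scale is dimensionless.
    """
    prob = _PLProblem(tree, [], n_sites, for_fitting=False)
    ages = np.asarray(ages, dtype=float)
    r = np.asarray(rates, dtype=float)
    if np.any(r <= 0):
        raise ValueError("rates must be positive")
    bn = prob.branch_nodes
    t = ages[prob.parent[bn]] - ages[bn]
    if np.any(t < -1e-9):
        raise ValueError("ages must satisfy parent > child")
    if r_ref is None:
        r_ref = float(r.mean())
    degenerate = (t <= 0) & (prob.x > _X_FLOOR)
    tt = np.maximum(t, _EPS_T)
    mu = r * tt * n_sites
    neg_loglik = -float(np.sum(prob.x * np.log(mu) - mu - prob._lgamma_x))
    if degenerate.any():
        neg_loglik = float("inf")
    has_parent = prob.parent_branch >= 0
    diffs = (r[has_parent] - r[prob.parent_branch[has_parent]]) / r_ref
    phi = float(np.sum(diffs * diffs))
    rc = prob.root_child_branches
    if len(rc) > 1:
        phi += float(np.var(r[rc] / r_ref))
    return neg_loglik, phi


def pl_objective(
    tree: dendropy.Tree,
    ages: np.ndarray,
    rates: np.ndarray,
    smoothing: float,
    n_sites: float,
    r_ref: float | None = None,
) -> float:
    """Penalized-likelihood objective ``-logL + smoothing * Phi``."""
    neg_loglik, phi = pl_objective_parts(tree, ages, rates, n_sites, r_ref)
    return neg_loglik + smoothing * phi


def fit_pl(
    tree: dendropy.Tree,
    constraints: list[CalibrationConstraint],
    smoothing: float,
    n_sites: float,
    n_restarts: int = 5,
    seed: int | np.random.Generator = 0,
    extra_starts: list[np.ndarray] | None = None,
    clock: bool = False,
) -> ChronogramFit:
    """Penalized-likelihood fit of node ages and branch rates.

    Multi-start bounded quasi-Newton (L-BFGS-B) over proportional node
    depths and log branch rates; the best of ``n_restarts`` (plus any
    warm starts) is kept, preferring the earlier start on ties. With
    ``clock=True`` a single shared rate is fitted (the Langley-Fitch
    clock), which also serves as the lambda -> infinity reference.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prob = _PLProblem(tree, constraints, n_sites)
    nf = prob.n_internal
    nr = 1 if clock else prob.n_branches
    r0 = prob.init_rate()

    def unpack(params):
        if clock:
            full = np.concatenate(
                [params[:nf], np.repeat(params[nf], prob.n_branches)]
            )
            return full
        return params

    def fun(params):
        value, grad = prob.objective_grad(unpack(params), smoothing)
        if clock:
            grad = np.concatenate([grad[:nf], [grad[nf:].sum()]])
        return value, grad

    starts = []
    base = np.concatenate([np.full(nf, 0.5), np.full(nr, np.log(r0))])
    starts.append(base)
    for _ in range(max(n_restarts - 1, 0)):
        f = rng.uniform(0.05, 0.95, size=nf)
        lr = np.log(r0) + rng.normal(0.0, 0.5, size=nr)
        starts.append(np.concatenate([f, lr]))
    for s in extra_starts or []:
        if len(s) == nf + nr:
            starts.append(np.asarray(s, dtype=float))

    bounds = [(1e-6, 1.0 - 1e-6)] * nf + [(-23.0, 5.0)] * nr
    best = None
    best_trace: list[list[float]] = []
    for start in starts:
        trace: list[float] = []

        def cb(xk):
            trace.append(fun(xk)[0])

        res = optimize.minimize(
            fun,
            x0=start,
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            callback=cb,
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
        )
        best_trace.append(trace)
        if best is None or res.fun < best.fun - 1e-6:
            best = res

    full_params = unpack(best.x)
    f = full_params[:nf]
    rates = np.exp(full_params[nf:])
    ages = prob.ages_from_fractions(f)
    ages, rates = _resolve_scale(prob, ages, rates)

    chrono = tree.clone(depth=1)
    cnodes = list(chrono.preorder_node_iter())
    for i, node in enumerate(cnodes):
        node.age = float(ages[i])
    for i, node in enumerate(cnodes):
        if node.parent_node is not None:
            node.edge.length = float(node.parent_node.age - node.age)

    fit = ChronogramFit(
        tree=chrono,
        node_ages={int(i): float(ages[i]) for i in prob.internal},
        rates=rates,
        smoothing=smoothing,
        objective=float(best.fun),
        converged=bool(best.success),
        n_sites=float(n_sites),
        objective_trace=best_trace,
        params=np.asarray(best.x, dtype=float),
    )
    _check_fit(fit, prob)
    return fit


def _resolve_scale(
    prob: _PLProblem, ages: np.ndarray, rates: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical point on the age/rate scale ridge.

    The branch likelihood depends on ages and rates only through
    ``mu = r * t * n_sites``, which is invariant under
    ``(ages * c, rates / c)``; with a scale-free penalty the objective is
    therefore exactly flat along this ridge and the absolute timescale
    is fixed only by the calibration boxes. The fit is reported at the
    midpoint of the feasible scaling interval, rather than wherever the
    optimizer happened to stop. Solutions with a pinned age
    (min == max) have a degenerate interval and are returned unchanged.
    """
    pos = ages > 0
    lo, hi = prob.lo, prob.hi
    lo_mask = pos & (lo > 0)
    hi_mask = pos & np.isfinite(hi)
    if not lo_mask.any() or not hi_mask.any():
        return ages, rates
    c_lo = float(np.max(lo[lo_mask] / ages[lo_mask]))
    c_hi = float(np.min(hi[hi_mask] / ages[hi_mask]))
    if c_hi < c_lo:  # numerically pinned
        return ages, rates
    c = 0.5 * (c_lo + c_hi)
    return ages * c, rates / c


def fit_clock(
    tree: dendropy.Tree,
    constraints: list[CalibrationConstraint],
    n_sites: float,
    n_restarts: int = 3,
    seed: int | np.random.Generator = 0,
) -> ChronogramFit:
    """Single-rate (Langley-Fitch) clock fit; the penalty vanishes."""
    return fit_pl(
        tree,
        constraints,
        smoothing=0.0,
        n_sites=n_sites,
        n_restarts=n_restarts,
        seed=seed,
        clock=True,
    )


def _check_fit(fit: ChronogramFit, prob: _PLProblem, tol: float = 1e-6) -> None:
    ages = np.array(
        [node.age for node in fit.tree.preorder_node_iter()]
    )
    for k, b in enumerate(prob.branch_nodes):
        if ages[prob.parent[b]] <= ages[b] - tol:
            raise RuntimeError("fitted chronogram violates parent > child age")
    if np.any(ages < prob.lo - 1e-4) or np.any(ages > prob.hi + 1e-4):
        raise RuntimeError("fitted chronogram violates a calibration box")
    if np.any(fit.rates <= 0):
        raise RuntimeError("non-positive fitted rate")


# ---------------------------------------------------------------------------
# Cross-validation of the smoothing parameter


def default_lambda_grid() -> np.ndarray:
    """Log-spaced grid from 1e5 down to 1e-3."""
    return np.logspace(5, -3, 9)


def _prune_tip(tree: dendropy.Tree, label: str):
    """Remove one tip, merging the resulting unifurcation.

    Returns (pruned tree, sibling subtree root label set, fraction of the
    merged branch above the vanished parent, pruned branch length).
    """
    work = tree.clone(depth=1)
    tip = None
    for lf in work.leaf_node_iter():
        if lf.taxon.label == label:
            tip = lf
            break
    if tip is None:
        raise ValueError(f"tip {label!r} not in tree")
    parent = tip.parent_node
    x_tip = tip.edge.length or 0.0
    siblings = [c for c in parent.child_nodes() if c is not tip]
    sib = siblings[0]
    b_sib = sib.edge.length or 0.0
    grand = parent.parent_node
    parent.remove_child(tip)
    if grand is None:
        # parent was the root: the sibling subtree becomes the tree
        parent.remove_child(sib)
        sib.parent_node = None
        work.seed_node = sib
        sib.edge.length = None
        frac = 0.0
        sib_tips = frozenset(lf.taxon.label for lf in sib.leaf_iter())
        work.taxon_namespace = tree.taxon_namespace
        return work, sib_tips, frac, x_tip, True
    b_par = parent.edge.length or 0.0
    grand.remove_child(parent)
    grand.add_child(sib)
    sib.edge.length = b_par + b_sib
    denom = b_par + b_sib
    frac = b_par / denom if denom > 0 else 0.5
    sib_tips = frozenset(lf.taxon.label for lf in sib.leaf_iter())
    return work, sib_tips, frac, x_tip, False


def cross_validate_lambda(
    tree: dendropy.Tree,
    constraints: list[CalibrationConstraint],
    n_sites: float,
    lambda_grid: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 2,
) -> tuple[list[dict], float]:
    """Leave-one-tip-out cross-validation of the smoothing parameter.

    For each tip and each lambda: the tip is pruned, the reduced tree
    fitted, and the pruned branch's substitution count predicted from
    the fitted rate of the merged branch and the interpolated age of the
    vanished attachment node; the score is the chi-square sum
    ``(observed - expected)^2 / expected`` over tips. Tips attached
    directly to the root are not scored: pruning one leaves no node
    carrying the root calibration at the original attachment age, so
    their prediction is unidentifiable. Returns the per-lambda table and
    the argmin lambda (ties to the larger lambda).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = np.asarray(
        default_lambda_grid() if lambda_grid is None else lambda_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    all_tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(all_tips) < 4:
        raise ValueError("cross-validation needs >= 4 tips")
    tips = [
        lf.taxon.label
        for lf in tree.leaf_node_iter()
        if lf.parent_node is not tree.seed_node
    ]

    pruned = {label: _prune_tip(tree, label) for label in tips}
    results = []
    warm: dict[str, np.ndarray] = {}
    first = True
    for lam in sorted(grid, reverse=True):  # large -> small, warm-starting
        score = 0.0
        for label in tips:
            work, sib_tips, frac, x_tip, was_root = pruned[label]
            fit = fit_pl(
                work,
                constraints,
                smoothing=lam,
                n_sites=n_sites,
                n_restarts=n_restarts if first else 1,
                seed=rng,
                extra_starts=[warm[label]] if label in warm else None,
            )
            warm[label] = fit.params
            expected = _predict_pruned(fit, sib_tips, frac, was_root)
            x_obs = x_tip * n_sites
            expected = max(expected, _X_FLOOR)
            score += (x_obs - expected) ** 2 / expected
        results.append({"lambda": float(lam), "cv_score": float(score)})
        first = False

    best = min(results, key=lambda r: (r["cv_score"], -r["lambda"]))
    return results, float(best["lambda"])


def _predict_pruned(
    fit: ChronogramFit, sib_tips: frozenset[str], frac: float, was_root: bool
) -> float:
    """Expected substitutions on the pruned branch under the fitted model."""
    tree = fit.tree
    if len(sib_tips) == 1:
        (label,) = sib_tips
        node = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == label
        )
    else:
        taxa = [t for t in tree.taxon_namespace if t.label in sib_tips]
        node = tree.mrca(taxa=taxa)
    branch_index = {id(n): k for k, n in enumerate(tree.preorder_node_iter())}
    # rate of the edge above the sibling subtree root
    rates_by_node = {}
    k = 0
    for n in tree.preorder_node_iter():
        if n.parent_node is not None:
            rates_by_node[id(n)] = fit.rates[k]
            k += 1
    if was_root or node.parent_node is None:
        # attachment at the (old) root: use the mean rate of the new root's
        # child edges and the fitted root age
        child_rates = [rates_by_node[id(c)] for c in node.child_nodes()]
        rate = float(np.mean(child_rates)) if child_rates else float(np.mean(fit.rates))
        age_attach = float(node.age)
    else:
        rate = float(rates_by_node[id(node)])
        age_top = float(node.parent_node.age)
        age_bot = float(node.age)
        age_attach = age_top - frac * (age_top - age_bot)
    return rate * age_attach * fit.n_sites
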