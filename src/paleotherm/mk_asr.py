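"""Binary-state Mk model: likelihood, rate fitting, marginal ASR.

State 0 is ectothermy, state 1 endothermy. The model is a two-state
continuous-time Markov chain with rates per Myr; transition probabilities
use the closed form for 2x2 generators, so no matrix exponential is
needed. Marginal ancestral states are computed with one post-order and one
pre-order pass, which is equivalent to rerooting the tree at every node
for reversible models.

All functions operate on a :class:`~paleotherm.tree_time.TimeScaledTree`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .tree_time import TimeScaledTree

__all__ = [
    "MkParams",
    "transition_probability",
    "tree_log_likelihood",
    "fit_rate_ml",
    "marginal_asr",
    "brute_force_asr",
    "ECTO",
    "ENDO",
]

ECTO, ENDO = 0, 1

RATE_LOWER = 1e-8
RATE_UPPER = 100.0

_STATE_ALIASES = {
    "0": 0, "1": 1,
    "ectothermy": 0, "endothermy": 1,
    "ecto": 0, "endo": 1,
}


def parse_state(value: object) -> int:
    """Normalize a state given as 0/1 or ectothermy/endothermy."""
    key = str(value).strip().lower()
    if key not in _STATE_ALIASES:
        raise ValueError(f"unrecognized state {value!r}")
    return _STATE_ALIASES[key]


def tip_vector(value: object) -> np.ndarray:
    """Tip input as a likelihood vector over (ectothermy, endothermy).

    Accepts a hard state (0/1 or a state name) or a length-2 probability
    vector (soft tip prior, e.g. ``(1 - p_end, p_end)``); vectors are
    normalized to sum to 1.
    """
    if isinstance(value, (list, tuple, np.ndarray)):
        vec = np.asarray(value, dtype=float)
        if vec.shape != (2,) or np.any(vec < 0) or vec.sum() <= 0:
            raise ValueError(f"invalid tip probability vector {value!r}")
        return vec / vec.sum()
    vec = np.zeros(2)
    vec[parse_state(value)] = 1.0
    return vec


@dataclass(frozen=True)
class MkParams:
    """Rates of the binary Mk model (per Myr) and root prior.

    ``model_form`` is ``"ER"`` (equal rates, q01 = q10) or ``"ARD"`` (all
    rates different). ``root_prior`` is ``"flat"`` (1/2, 1/2) or
    ``"stationary"`` (q10, q01)/(q01+q10).
    """

    q01: float
    q10: float
    model_form: str = "ER"
    root_prior: str = "flat"
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")
        if self.model_form not in ("ER", "ARD"):
            raise ValueError(f"unknown model_form {self.model_form!r}")
        if self.model_form == "ER" and self.q01 != self.q10:
            raise ValueError("ER model requires q01 == q10")
        if self.root_prior not in ("flat", "stationary"):
            raise ValueError(f"unknown root_prior {self.root_prior!r}")

    @classmethod
    def er(cls, q: float, root_prior: str = "flat") -> "MkParams":
        return cls(q01=q, q10=q, model_form="ER", root_prior=root_prior)

    def prior(self) -> np.ndarray:
        if self.root_prior == "flat":
            return np.array([0.5, 0.5])
        s = self.q01 + self.q10
        if s == 0.0:
            return np.array([0.5, 0.5])
        return np.array([self.q10 / s, self.q01 / s])


def transition_probability(t: float, params: MkParams) -> np.ndarray:
    """2x2 matrix ``P[i, j] = Pr(child state j | parent state i, t)``.

    Closed form for the generator ``[[-q01, q01], [q10, -q10]]``.
    """
    if t < 0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    q01, q10 = params.q01, params.q10
    s = q01 + q10
    if s == 0.0:
        return np.eye(2)
    e = np.exp(-s * t)
    return np.array(
        [
            [(q10 + q01 * e) / s, (q01 - q01 * e) / s],
            [(q10 - q10 * e) / s, (q01 + q10 * e) / s],
        ]
    )


def _check_states(
    ts: TimeScaledTree, states: Mapping[str, object]
) -> dict[str, np.ndarray]:
    tips = [lf.taxon.label for lf in ts.tree.leaf_node_iter()]
    missing = sorted(set(tips) - set(states))
    if missing:
        raise ValueError(f"missing tip state(s): {missing}")
    return {t: tip_vector(states[t]) for t in tips}


def _downpass(ts: TimeScaledTree, states: Mapping[str, object], params: MkParams):
    """Post-order conditional likelihoods, rescaled per node.

    Returns (down, log_scale) where ``down[nid]`` is the rescaled
    conditional likelihood of the subtree below nid given each state at
    nid, and ``log_scale`` is the accumulated log of the scalers.
    """
    st = _check_states(ts, states)
    ages = ts.ages
    down: dict[str, np.ndarray] = {}
    log_scale = 0.0
    for node in ts.tree.postorder_node_iter():
        if node.is_leaf():
            vec = st[node.taxon.label].copy()
        else:
            vec = np.ones(2)
            for child in node.child_nodes():
                t = ages[node.id] - ages[child.id]
                P = transition_probability(t, params)
                vec = vec * (P @ down[child.id])
            m = vec.max()
            if m <= 0.0:
                raise ValueError("zero likelihood encountered")
            vec = vec / m
            log_scale += np.log(m)
        down[node.id] = vec
    return down, log_scale


def tree_log_likelihood(
    ts: TimeScaledTree, states: Mapping[str, object], params: MkParams
) -> float:
    """Felsenstein pruning log-likelihood of the tip states."""
    down, log_scale = _downpass(ts, states, params)
    root_vec = down[ts.tree.seed_node.id]
    lik = float(params.prior() @ root_vec)
    if lik <= 0.0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def fit_rate_ml(
    ts: TimeScaledTree,
    states: Mapping[str, object],
    model_form: str = "ER",
    root_prior: str = "flat",
    tol: float = 1e-10,
) -> MkParams:
    """Maximum-likelihood transition rate(s), log-rate parameterized.

    Rates are bounded to [1e-8, 100] per Myr. If all tips share one state
    there is no signal: a warning is issued and the rate pinned at the
    lower bound.
    """
    st = _check_states(ts, states)
    hard = [int(v.argmax()) for v in st.values() if v.max() == 1.0]
    if len(hard) == len(st) and len(set(hard)) == 1:
        warnings.warn(
            "all tips share one state; rate pinned to lower bound",
            stacklevel=2,
        )
        if model_form == "ER":
            return MkParams.er(RATE_LOWER, root_prior=root_prior)
        return MkParams(RATE_LOWER, RATE_LOWER, model_form="ARD",
                        root_prior=root_prior)

    lo, hi = np.log(RATE_LOWER), np.log(RATE_UPPER)

    if model_form == "ER":
        def nll(logq: float) -> float:
            p = MkParams.er(float(np.exp(logq)), root_prior=root_prior)
            return -tree_log_likelihood(ts, st, p)

        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        q = float(np.exp(res.x))
        return MkParams(q, q, model_form="ER", root_prior=root_prior,
                        log_likelihood=float(-res.fun))

    if model_form == "ARD":
        def nll2(logq: np.ndarray) -> float:
            p = MkParams(float(np.exp(logq[0])), float(np.exp(logq[1])),
                         model_form="ARD", root_prior=root_prior)
            return -tree_log_likelihood(ts, st, p)

        best = None
        for start in ([-3.0, -3.0], [-1.0, -5.0], [-5.0, -1.0]):
            res = minimize(nll2, x0=np.array(start), method="L-BFGS-B",
                           bounds=[(lo, hi), (lo, hi)],
                           options={"ftol": tol})
            if best is None or res.fun < best.fun:
                best = res
        q01, q10 = np.exp(best.x)
        return MkParams(float(q01), float(q10), model_form="ARD",
                        root_prior=root_prior,
                        log_likelihood=float(-best.fun))

    raise ValueError(f"unknown model_form {model_form!r}")


def marginal_asr(
    ts: TimeScaledTree, states: Mapping[str, object], params: MkParams
) -> dict[str, np.ndarray]:
    """Marginal posterior state probabilities at every node.

    One post-order pass (conditional likelihoods of each subtree) and one
    pre-order pass (likelihood of the rest of the tree) are combined at
    each node; for reversible models this equals rerooting the tree at
    that node. Returns ``{node_id: array([p_ecto, p_endo])}`` with rows
    normalized; tips get probability 1 on their observed state.
    """
    down, _ = _downpass(ts, states, params)
    ages = ts.ages
    prior = params.prior()

    up: dict[str, np.ndarray] = {ts.tree.seed_node.id: prior.copy()}
    out: dict[str, np.ndarray] = {}
    for node in ts.tree.preorder_node_iter():
        children = node.child_nodes()
        # transition matrices and down-messages through each child branch
        msgs = {}
        for child in children:
            t = ages[node.id] - ages[child.id]
            P = transition_probability(t, params)
            msgs[child.id] = (P, P @ down[child.id])
        for child in children:
            partial = up[node.id].copy()
            for sib in children:
                if sib is not child:
                    partial = partial * msgs[sib.id][1]
            P = msgs[child.id][0]
            vec = partial @ P  # sum over parent state i of partial[i] P[i, j]
            m = vec.max()
            up[child.id] = vec / m if m > 0 else vec
        post = up[node.id] * down[node.id]
        total = post.sum()
        if total <= 0.0:
            raise ValueError(f"zero posterior at node {node.id!r}")
        out[node.id] = post / total
    return out


def brute_force_asr(
    ts: TimeScaledTree, states: Mapping[str, object], params: MkParams
) -> dict[str, np.ndarray]:
    """Exhaustive-enumeration oracle for :func:`marginal_asr`.

    Enumerates every assignment of states to internal nodes, weights each
    by prior times path probabilities, and marginalizes per node. Only
    valid for trees with at most 12 internal nodes.
    """
    st = _check_states(ts, states)
    internal = [n for n in ts.tree.preorder_node_iter() if not n.is_leaf()]
    if len(internal) > 12:
        raise ValueError(
            f"{len(internal)} internal nodes; brute force capped at 12"
        )
    ages = ts.ages
    prior = params.prior()
    root_id = ts.tree.seed_node.id

    # precompute transition matrices per branch
    P: dict[str, np.ndarray] = {}
    for node in ts.tree.preorder_node_iter():
        if node.parent_node is not None:
            t = ages[node.parent_node.id] - ages[node.id]
            P[node.id] = transition_probability(t, params)

    leaves = ts.tree.leaf_nodes()
    acc = {n.id: np.zeros(2) for n in internal}
    acc.update({lf.id: np.zeros(2) for lf in leaves})
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = {n.id: s for n, s in zip(internal, combo)}
        w = prior[assign[root_id]]
        tip_parts: dict[str, np.ndarray] = {}
        for node in ts.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            ps = assign[node.parent_node.id]
            if node.is_leaf():
                # marginalize the tip state against its (possibly soft) prior
                part = P[node.id][ps] * st[node.taxon.label]
                tip_parts[node.id] = part
                w *= part.sum()
            else:
                w *= P[node.id][ps, assign[node.id]]
        total += w
        for nid, s in assign.items():
            acc[nid][s] += w
        for nid, part in tip_parts.items():
            psum = part.sum()
            if psum > 0.0:
                acc[nid] += w * part / psum
    if total <= 0.0:
        raise ValueError("zero total likelihood in brute force")

    return {nid: v / total for nid, v in acc.items()}
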