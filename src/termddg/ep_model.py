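"""The regularized statistical energy model over sub-TERM match ensembles.

The effective statistical energy of amino acid x at the seed position is
a self energy parameter (sEP) J_x plus, for each contacting position j
covered by a given match, a pair energy parameter (pEP) J_{x, y} keyed by
the amino acid y the match carries at j. Match sequences are modelled by
a softmax over the 20 amino acids,

    P_m(x) = exp(-E_m(x)) P0(x) / Z_m,

and parameters are fit by minimizing the ensemble-weighted mean negative
log-probability of the observed seed amino acids, with a quadratic
regularizer that pins sparsely observed parameters to prior values (zero
for sEPs, a generic contact potential for pEPs):

    L = L0 + lambda * sum_p (J(p) - Jhat(p))^2 / (O(p) + 1),

where O(p) counts how often the sequence pattern behind p occurs across
all retained matches. Optimization is block-coordinate over 1 + |C|
parameter groups (the 20 sEPs, then the 400 pEPs of each contact).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from termddg.structure_io import AA_INDEX, AMINO_ACIDS, AminoAcidDistribution
from termddg.term_engine import Match, MatchEnsemble, Term

logger = logging.getLogger(__name__)

W_CONST = 1000.0
DEFAULT_LAMBDA = 1000.0


@dataclass
class EPSet:
    """Self and pair energy parameters for one seed position.

    ``contacts`` are the structure positions of the seed's full contact set
    C; ``pEP[j]`` is the 20x20 matrix indexed [seed aa, contact aa].
    """

    contacts: tuple[int, ...]
    sEP: np.ndarray  # (20,)
    pEP: dict[int, np.ndarray]  # j -> (20, 20)
    prior_sEP: np.ndarray
    prior_pEP: dict[int, np.ndarray]
    occ_sEP: np.ndarray | None = None  # (20,)
    occ_pEP: dict[int, np.ndarray] | None = None

    @classmethod
    def from_priors(
        cls,
        contacts: tuple[int, ...],
        pair_priors: dict[int, np.ndarray] | None = None,
        self_priors: np.ndarray | None = None,
    ) -> "EPSet":
        """Initialize all parameters at their priors (sEP default zero)."""
        s_prior = np.zeros(20) if self_priors is None else np.asarray(self_priors, float).copy()
        p_prior = {
            j: (np.zeros((20, 20)) if pair_priors is None or j not in pair_priors
                else np.asarray(pair_priors[j], float).copy())
            for j in contacts
        }
        return cls(
            contacts=tuple(contacts),
            sEP=s_prior.copy(),
            pEP={j: p.copy() for j, p in p_prior.items()},
            prior_sEP=s_prior,
            prior_pEP=p_prior,
        )

    def copy(self) -> "EPSet":
        return EPSet(
            self.contacts,
            self.sEP.copy(),
            {j: m.copy() for j, m in self.pEP.items()},
            self.prior_sEP.copy(),
            {j: m.copy() for j, m in self.prior_pEP.items()},
            None if self.occ_sEP is None else self.occ_sEP.copy(),
            None if self.occ_pEP is None else {j: m.copy() for j, m in self.occ_pEP.items()},
        )

    def n_parameters(self) -> int:
        return 20 + 400 * len(self.contacts)


@dataclass
class EnsembleCollection:
    """Sub-TERM ensembles entering one fit, with their reliability weights.

    ``native_context`` maps each contact position to the amino acid the
    studied protein carries there (sigma_0).
    """

    ensembles: list[tuple[Term, MatchEnsemble]]
    native_context: dict[int, str]
    w_const: float = W_CONST

    def weights(self) -> np.ndarray:
        return np.array(
            [len(e.matches) / (len(e.matches) + self.w_const) for _, e in self.ensembles]
        )

    @property
    def contacts(self) -> tuple[int, ...]:
        out: set[int] = set()
        for term, _ in self.ensembles:
            out.update(term.contacts)
        return tuple(sorted(out))

    def capped(self, max_order: int) -> "EnsembleCollection":
        """Model variant: keep only sub-TERMs up to the given order."""
        kept = [(t, e) for t, e in self.ensembles if t.order <= max_order]
        return EnsembleCollection(kept, dict(self.native_context), self.w_const)


def match_energy(eps: EPSet, term: Term, match: Match, x: str) -> float:
    """E_m(x): self energy plus pair energies against the match's context."""
    xi = AA_INDEX[x]
    e = float(eps.sEP[xi])
    cidx = term.contact_indices()
    for j in term.contacts:
        y = match.sequence[cidx[j]]
        e += float(eps.pEP[j][xi, AA_INDEX[y]])
    return e


def match_probability(eps: EPSet, term: Term, match: Match, P0: AminoAcidDistribution) -> np.ndarray:
    """Softmax distribution over the seed amino acid for one match."""
    E = np.array([match_energy(eps, term, match, a) for a in AMINO_ACIDS])
    logit = -E + np.log(P0.freq)
    logit -= logsumexp(logit)
    return np.exp(logit)


# -- vectorized internal representation ------------------------------------

@dataclass
class _EnsembleData:
    contacts: tuple[int, ...]  # this sub-TERM's contacts
    ctx: np.ndarray  # (M, k) context aa indices, column order == contacts
    seeds: np.ndarray  # (M,) observed seed aa indices
    weight: float  # w_s


def _prepare(collection: EnsembleCollection) -> list[_EnsembleData]:
    data = []
    ws = collection.weights()
    for (term, ens), w in zip(collection.ensembles, ws):
        if not ens.matches:
            continue
        cidx = term.contact_indices()
        ctx = np.array(
            [[AA_INDEX[m.sequence[cidx[j]]] for j in term.contacts] for m in ens.matches],
            dtype=int,
        ).reshape(len(ens.matches), len(term.contacts))
        seeds = np.array([AA_INDEX[m.seed_aa] for m in ens.matches], dtype=int)
        data.append(_EnsembleData(term.contacts, ctx, seeds, float(w)))
    return data


def _energies(eps: EPSet, d: _EnsembleData) -> np.ndarray:
    """(M, 20) energy matrix for every match and candidate seed amino acid."""
    E = np.broadcast_to(eps.sEP, (len(d.seeds), 20)).copy()
    for col, j in enumerate(d.contacts):
        E += eps.pEP[j][:, d.ctx[:, col]].T
    return E


def _nll_terms(eps: EPSet, data: list[_EnsembleData], logp0: np.ndarray):
    """Per-ensemble mean NLL of observed seeds and the posterior matrices."""
    nlls, posts = [], []
    for d in data:
        logit = -_energies(eps, d) + logp0
        lse = logsumexp(logit, axis=1)
        nll = lse - logit[np.arange(len(d.seeds)), d.seeds]
        nlls.append(float(nll.mean()))
        posts.append(np.exp(logit - lse[:, None]))
    return nlls, posts


def _reg_value(eps: EPSet, lam: float) -> float:
    occ_s = eps.occ_sEP if eps.occ_sEP is not None else np.zeros(20)
    v = float(np.sum((eps.sEP - eps.prior_sEP) ** 2 / (occ_s + 1.0)))
    for j in eps.contacts:
        occ = eps.occ_pEP[j] if eps.occ_pEP is not None else np.zeros((20, 20))
        v += float(np.sum((eps.pEP[j] - eps.prior_pEP[j]) ** 2 / (occ + 1.0)))
    return lam * v


def objective(
    eps: EPSet,
    collection: EnsembleCollection,
    lam: float,
    P0: AminoAcidDistribution,
) -> float:
    """The full regularized objective L = L0 + lam * sum (J-Jhat)^2/(O+1)."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    data = _prepare(collection)
    logp0 = np.log(P0.freq)
    if data:
        nlls, _ = _nll_terms(eps, data, logp0)
        w = np.array([d.weight for d in data])
        l0 = float(np.dot(w, nlls) / w.sum())
    else:
        l0 = 0.0
    return l0 + _reg_value(eps, lam)


def count_occurrences(eps: EPSet, collection: EnsembleCollection) -> None:
    """Fill occurrence counts O(p) from the retained matches, in place.

    O(sEP_x): matches (over all ensembles) whose seed amino acid is x.
    O(pEP_j[x, y]): matches in ensembles covering contact j whose seed is x
    and whose residue aligned to j is y. Each match counts once.
    """
    occ_s = np.zeros(20)
    occ_p = {j: np.zeros((20, 20)) for j in eps.contacts}
    for term, ens in collection.ensembles:
        cidx = term.contact_indices()
        for m in ens.matches:
            xi = AA_INDEX[m.seed_aa]
            occ_s[xi] += 1
            for j in term.contacts:
                occ_p[j][xi, AA_INDEX[m.sequence[cidx[j]]]] += 1
    eps.occ_sEP = occ_s
    eps.occ_pEP = occ_p


@dataclass
class FitConfig:
    lam: float = DEFAULT_LAMBDA
    max_cycles: int = 100
    objective_tol: float = 1e-5
    param_tol: float = 0.01  # l2 norm of per-group parameter change
    inner_maxiter: int = 200
    method: str = "L-BFGS-B"  # or "Nelder-Mead" to mirror a simplex search
    center_seps: bool = True


def _group_objective_grad(theta, group, eps, data, logp0, lam, w_norm):
    """Objective and gradient as a function of one parameter group."""
    if group == "self":
        eps.sEP = theta.reshape(20)
    else:
        eps.pEP[group] = theta.reshape(20, 20)
    total = 0.0
    if group == "self":
        grad = np.zeros(20)
    else:
        grad = np.zeros((20, 20))
    for d in data:
        if group != "self" and group not in d.contacts:
            continue
        logit = -_energies(eps, d) + logp0
        lse = logsumexp(logit, axis=1)
        M = len(d.seeds)
        nll = lse - logit[np.arange(M), d.seeds]
        total += d.weight / w_norm * float(nll.mean())
        post = np.exp(logit - lse[:, None])  # (M, 20)
        resid = -post
        resid[np.arange(M), d.seeds] += 1.0  # one-hot minus posterior
        scale = d.weight / (w_norm * M)
        if group == "self":
            grad += scale * resid.sum(axis=0)
        else:
            col = d.contacts.index(group)
            ctx = d.ctx[:, col]
            np.add.at(grad.T, ctx, scale * resid)
    # regularization for this group only (other groups are constants)
    if group == "self":
        occ = eps.occ_sEP if eps.occ_sEP is not None else np.zeros(20)
        diff = eps.sEP - eps.prior_sEP
        total += lam * float(np.sum(diff**2 / (occ + 1.0)))
        grad += 2.0 * lam * diff / (occ + 1.0)
    else:
        occ = eps.occ_pEP[group] if eps.occ_pEP is not None else np.zeros((20, 20))
        diff = eps.pEP[group] - eps.prior_pEP[group]
        total += lam * float(np.sum(diff**2 / (occ + 1.0)))
        grad += 2.0 * lam * diff / (occ + 1.0)
    return total, grad.ravel()


def fit_eps(
    collection: EnsembleCollection,
    priors: EPSet,
    lam: float = DEFAULT_LAMBDA,
    P0: AminoAcidDistribution | None = None,
    config: FitConfig | None = None,
) -> EPSet:
    """Block-coordinate descent over the 1 + |C| parameter groups.

    Starts at the priors, visits the sEP group then each contact's pEP
    group per cycle, and stops when the between-cycle objective improvement
    falls below ``objective_tol`` or every group's parameter change has l2
    norm below ``param_tol`` (or at ``max_cycles``). Fitted sEPs are
    mean-centered afterwards: the match probabilities are invariant to a
    constant shift, so centering only fixes the reporting gauge.
    """
    config = config or FitConfig()
    if P0 is None:
        P0 = AminoAcidDistribution.uniform()
    eps = priors.copy()
    count_occurrences(eps, collection)
    data = _prepare(collection)
    if not data:
        warnings.warn("no matches in any ensemble; returning priors unchanged")
        return eps
    logp0 = np.log(P0.freq)
    w_norm = float(sum(d.weight for d in data))
    groups: list = ["self"] + list(eps.contacts)

    def full_objective() -> float:
        nlls, _ = _nll_terms(eps, data, logp0)
        w = np.array([d.weight for d in data])
        return float(np.dot(w, nlls) / w.sum()) + _reg_value(eps, lam)

    prev = full_objective()
    for cycle in range(config.max_cycles):
        group_deltas = []
        for g in groups:
            theta0 = (eps.sEP if g == "self" else eps.pEP[g]).ravel().copy()
            if config.method == "Nelder-Mead":
                res = minimize(
                    lambda t: _group_objective_grad(t, g, eps, data, logp0, lam, w_norm)[0],
                    theta0,
                    method="Nelder-Mead",
                    options={"maxiter": config.inner_maxiter * len(theta0)},
                )
            else:
                res = minimize(
                    _group_objective_grad,
                    theta0,
                    args=(g, eps, data, logp0, lam, w_norm),
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": config.inner_maxiter},
                )
            theta = res.x
            if g == "self":
                eps.sEP = theta.reshape(20)
            else:
                eps.pEP[g] = theta.reshape(20, 20)
            group_deltas.append(float(np.linalg.norm(theta - theta0)))
        cur = full_objective()
        if prev - cur < config.objective_tol:
            break
        if all(d < config.param_tol for d in group_deltas):
            break
        prev = cur
    if config.center_seps:
        eps.sEP = eps.sEP - eps.sEP.mean()
    return eps


@dataclass
class PredictionResult:
    """A predicted stability change plus its decomposition and confidence."""

    mutation: tuple[str, str]  # (u, v)
    ddg: float  # statistical-energy units; positive = destabilizing
    ubiquity: float
    self_contribution: float
    pair_contributions: dict[int, float]
    model_tag: str = "full"


def predict_ddg(
    eps: EPSet,
    native_context: dict[int, str],
    u: str,
    v: str,
    model_tag: str = "full",
) -> PredictionResult:
    """ddG(u -> v) = E(v | sigma_0) - E(u | sigma_0) under the fitted EPs."""
    ui, vi = AA_INDEX[u], AA_INDEX[v]
    self_c = float(eps.sEP[vi] - eps.sEP[ui])
    pair_c = {}
    for j in eps.contacts:
        yj = AA_INDEX[native_context[j]]
        pair_c[j] = float(eps.pEP[j][vi, yj] - eps.pEP[j][ui, yj])
    ddg = self_c + sum(pair_c.values())
    nu = ubiquity(eps, native_context, u, v) if eps.occ_sEP is not None else 0.0
    return PredictionResult((u, v), ddg, nu, self_c, pair_c, model_tag)


def ubiquity(eps: EPSet, native_context: dict[int, str], u: str, v: str) -> float:
    """Occurrence-based confidence: how well either end state of the
    mutation is represented in the retained match statistics."""
    if eps.occ_sEP is None:
        raise ValueError("occurrences not populated; fit or count first")
    vals = []
    for a in (u, v):
        ai = AA_INDEX[a]
        term = float(eps.occ_sEP[ai]) / 20.0
        if eps.contacts:
            pair_sum = sum(
                float(eps.occ_pEP[j][ai, AA_INDEX[native_context[j]]]) for j in eps.contacts
            )
            term += pair_sum / len(eps.contacts)
        vals.append(term)
    return max(vals)
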