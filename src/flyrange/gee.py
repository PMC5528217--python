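"""Binomial-logit GEE with pluggable working correlations, and Pan's QIC.

The estimating equations

    sum_c D_c' V_c^{-1} (y_c - mu_c) = 0,   V_c = phi A_c^{1/2} R_c A_c^{1/2}

are solved by iteratively reweighted updates, with A = mu(1-mu) the
binomial variance function and R_c the working correlation of cluster c
(independence, exchangeable, or a fixed matrix such as the Brownian-motion
phylogenetic correlation).  The robust (sandwich) covariance is

    V_R = S^{-1} M S^{-1},  S = sum_c D_c'V_c^{-1}D_c,
    M = sum_c D_c'V_c^{-1} r_c r_c' V_c^{-1}D_c,  r_c = y_c - mu_c,

and model selection uses the quasi-likelihood under the independence
model criterion

    QIC = -2 Q(beta) + 2 trace(Omega_I V_R),

where Q is the independence binomial quasi-likelihood and Omega_I = X'AX
is the model-based information computed under the independence structure
at the fitted coefficients.

Saturated designs (one parameter per observation, as in the per-plant
interaction models) are perfectly separated by construction; such fits are
stabilized by a small ridge penalty and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import Dataset, RunConfig, ValidationError
from .matrices import PresenceMatrix
from .phylo import PhyloCorrelation

logger = logging.getLogger(__name__)

MODEL_IDS = ("M1", "M2", "M3", "M4")
SEPARATION_ETA = 30.0
DEFAULT_RIDGE = 1e-4
MU_CLIP = 1e-12


@dataclass
class FixedCorrelation:
    """A fixed working correlation shared by all clusters.

    ``positions[k]`` maps observation k to a row/column of ``matrix``;
    cluster c uses the submatrix at its members' positions.
    """

    matrix: np.ndarray
    positions: np.ndarray  # (n,) int

    def block(self, members: np.ndarray) -> np.ndarray:
        pos = self.positions[members]
        return self.matrix[np.ix_(pos, pos)]

    def block_inverse(self, members: np.ndarray, rel_floor: float = 1e-8) -> np.ndarray:
        """Stable inverse of a correlation block.

        Phylogenetic correlations are often near-singular (recently
        diverged tips are correlated almost 1), so eigenvalues below
        ``rel_floor`` times the largest are floored before inverting.
        """
        r = self.block(members)
        vals, vecs = np.linalg.eigh(r)
        floor = rel_floor * float(vals.max())
        vals = np.maximum(vals, floor)
        return (vecs / vals) @ vecs.T


@dataclass
class GEEDesign:
    y: np.ndarray  # (n,) binary (or proportions with weights)
    X: np.ndarray  # (n, p)
    clusters: np.ndarray  # (n,) labels
    working: str | FixedCorrelation = "independence"  # or "exchangeable"
    weights: np.ndarray | None = None  # binomial denominators, default 1

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.clusters = np.asarray(self.clusters)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X and y length mismatch")
        if self.clusters.shape[0] != self.y.shape[0]:
            raise ValidationError("clusters and y length mismatch")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class GEEFit:
    beta: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    phi: float
    quasi_lik: float
    omega_independence: np.ndarray  # X'AX at beta-hat
    n_iter: int
    converged: bool
    ridge: float = 0.0
    separation: bool = False
    n_obs: int = 0
    n_params: int = 0
    rho: float | None = None  # exchangeable correlation, when estimated


def quasi_likelihood(y: np.ndarray, mu: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Independence binomial quasi-likelihood sum y log mu + (1-y) log(1-mu)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValidationError("y and mu length mismatch")
    mu = np.clip(mu, MU_CLIP, 1.0 - MU_CLIP)
    q = y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)
    if weights is not None:
        q = q * np.asarray(weights, dtype=float)
    return float(q.sum())


def _cluster_index(clusters: np.ndarray) -> list[np.ndarray]:
    order = {}
    for k, c in enumerate(clusters):
        order.setdefault(c, []).append(k)
    return [np.asarray(v, dtype=int) for v in order.values()]


def fit_gee(
    design: GEEDesign,
    max_iter: int = 200,
    tol: float = 1e-8,
    ridge: float = 0.0,
    phi: float | None = 1.0,
) -> GEEFit:
    """Solve the GEE by iteratively reweighted updates.

    ``phi=1`` (the binary-data convention) by default; pass ``None`` to
    use the Pearson moment estimator.  If the linear predictor runs away
    (|eta| > 30, i.e. separation), a small ridge penalty is engaged and
    the fit is flagged rather than aborted.
    """
    y, X = design.y, design.X
    n, p = X.shape
    w = design.weights if design.weights is not None else np.ones(n)
    members = _cluster_index(design.clusters)
    exchangeable = design.working == "exchangeable"
    fixed = isinstance(design.working, FixedCorrelation)

    # pre-invert fixed correlation blocks once (they never change)
    blocks_inv: list[np.ndarray] | None = None
    if fixed:
        blocks_inv = [design.working.block_inverse(m) for m in members]

    state = {"rho": 0.0, "phi": 1.0 if phi is None else phi}

    def _assemble(b: np.ndarray, lam: float):
        """Hessian-like matrix H, penalized score, and per-cluster scores."""
        eta = X @ b
        mu = expit(eta)
        a = np.clip(mu * (1.0 - mu), 1e-10, None) * w
        sa = np.sqrt(a)
        z = (y - mu) * w / sa  # Pearson-scaled residuals
        if phi is None:
            state["phi"] = float((z @ z) / max(n - p, 1))
        if exchangeable:
            num, den = 0.0, 0
            for m in members:
                zc = z[m]
                s = zc.sum()
                num += (s * s - (zc * zc).sum()) / 2.0
                den += len(m) * (len(m) - 1) // 2
            rho = num / (den * state["phi"]) if den else 0.0
            state["rho"] = float(np.clip(rho, -0.99, 0.99))
        H = np.zeros((p, p))
        scores = np.zeros((p, len(members)))
        for ci, m in enumerate(members):
            U = sa[m, None] * X[m]  # A^{1/2} X
            if fixed:
                Rz = blocks_inv[ci] @ z[m]
                RU = blocks_inv[ci] @ U
            elif exchangeable and len(m) > 1:
                k = len(m)
                Rc = np.full((k, k), state["rho"])
                np.fill_diagonal(Rc, 1.0)
                Rz = np.linalg.solve(Rc, z[m])
                RU = np.linalg.solve(Rc, U)
            else:
                Rz, RU = z[m], U
            H += U.T @ RU
            scores[:, ci] = U.T @ Rz
        score = scores.sum(axis=1) - lam * b
        return H, score, scores, float(np.max(np.abs(eta)))

    beta = np.zeros(p)
    lam = ridge
    separation = False
    n_iter = 0
    converged = False
    eta_history: list[float] = []
    H, score, _, max_eta = _assemble(beta, lam)
    for n_iter in range(1, max_iter + 1):
        eta_history.append(max_eta)
        # separation: the linear predictor either blows past the hard
        # threshold or keeps creeping outward (quasi-separation)
        creeping = (
            n_iter > 20
            and max_eta > 12.0
            and all(b > a for a, b in zip(eta_history[-8:], eta_history[-7:]))
        )
        if not separation and (max_eta > SEPARATION_ETA or creeping):
            separation = True
            if lam == 0.0:
                lam = DEFAULT_RIDGE
                logger.warning(
                    "separation detected (max |eta| = %.1f); ridge %.0e engaged",
                    max_eta, lam,
                )
                H, score, _, max_eta = _assemble(beta, lam)
        norm0 = float(np.max(np.abs(score)))
        if norm0 < 1e-8:  # estimating equations solved
            converged = True
            break
        step = np.linalg.solve(H + lam * np.eye(p), score)
        # backtracking on the penalized score norm keeps strongly coupled
        # (fixed-R, saturated) systems from oscillating
        scale = 1.0
        for _ in range(30):
            trial = beta + scale * step
            H_t, score_t, _, eta_t = _assemble(trial, lam)
            if float(np.max(np.abs(score_t))) <= norm0 or norm0 < tol:
                break
            scale *= 0.5
        beta = beta + scale * step
        H, score, max_eta = H_t, score_t, eta_t
        if scale * float(np.max(np.abs(step))) < tol:
            converged = True
            break
    if not converged:
        logger.warning("GEE did not converge in %d iterations", max_iter)

    # covariances at the solution
    S, _, scores, _ = _assemble(beta, lam)
    eta = X @ beta
    mu = expit(eta)
    a = np.clip(mu * (1.0 - mu), 1e-10, None) * w
    phi_hat = state["phi"]
    S_pen = S + lam * np.eye(p)
    try:
        S_inv = np.linalg.inv(S_pen / phi_hat)
    except np.linalg.LinAlgError as err:
        raise ValidationError(
            "singular GEE information; prune degenerate design columns"
        ) from err
    cov_model = S_inv
    # sandwich as L L' so it is PSD by construction even when S is
    # badly conditioned (saturated ridge-stabilized fits)
    L = S_inv @ (scores / phi_hat)
    cov_robust = L @ L.T

    omega_I = X.T @ (a[:, None] * X) / phi_hat
    q = quasi_likelihood(y, mu, weights=w if design.weights is not None else None)
    return GEEFit(
        beta=beta,
        cov_model=cov_model,
        cov_robust=cov_robust,
        phi=phi_hat,
        quasi_lik=q,
        omega_independence=omega_I,
        n_iter=n_iter,
        converged=converged,
        ridge=lam,
        separation=separation,
        n_obs=n,
        n_params=p,
        rho=state["rho"] if exchangeable else None,
    )


def qic(fit: GEEFit) -> float:
    """Pan's QIC = -2Q + 2 trace(Omega_I V_robust)."""
    trace = float(np.trace(fit.omega_independence @ fit.cov_robust))
    return -2.0 * fit.quasi_lik + 2.0 * trace


@dataclass
class QICTable:
    """QIC per candidate model plus the delta-rule selection outcome."""

    rows: pd.DataFrame  # model_id, qic, n_params, note
    selected: str = "inconclusive"
    within_delta: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.sort_values("qic").reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
        return out

    def to_dict(self) -> dict:
        return {
            "rows": self.to_frame().to_dict(orient="records"),
            "selected": self.selected,
            "within_delta": self.within_delta,
        }


def select_model(table: QICTable, config: RunConfig) -> str:
    """Lowest-QIC model, decisive only when the runner-up trails by more
    than ``qic_delta``; otherwise 'inconclusive' (ties included)."""
    rows = table.rows.sort_values("qic")
    best = rows.iloc[0]
    within = rows[rows["qic"] <= best["qic"] + config.qic_delta]["model_id"].tolist()
    table.within_delta = within
    if len(rows) > 1 and rows.iloc[1]["qic"] - best["qic"] > config.qic_delta:
        table.selected = str(best["model_id"])
    else:
        table.selected = "inconclusive"
    return table.selected


# ---------------------------------------------------------------------------
# the M1-M4 community-structure model suite
# ---------------------------------------------------------------------------


def _dummies(labels: list, levels: list) -> np.ndarray:
    """Drop-first treatment coding."""
    out = np.zeros((len(labels), max(len(levels) - 1, 0)))
    pos = {lv: i for i, lv in enumerate(levels)}
    for r, lab in enumerate(labels):
        i = pos[lab]
        if i > 0:
            out[r, i - 1] = 1.0
    return out


def _per_fruit_cells(
    dataset: Dataset, period: str, plants: list[str], flies: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate per-fruit presence to binomial cells.

    Returns ``k`` (plants x flies: fruits in which the fly emerged) and
    ``n`` (plants: fruits sampled).  Fitting weighted cell proportions is
    numerically identical to fitting one binary row per (fruit, fly).
    """
    plant_pos = {p: j for j, p in enumerate(plants)}
    fly_pos = {f: i for i, f in enumerate(flies)}
    k = np.zeros((len(plants), len(flies)))
    n = np.zeros(len(plants))
    for s in dataset.samples:
        if s.period != period or s.plant_id not in plant_pos:
            continue
        j = plant_pos[s.plant_id]
        n[j] += 1
        for f, c in s.counts.items():
            if c >= 1 and f in fly_pos:
                k[j, fly_pos[f]] += 1
    if np.any(n == 0):
        bad = [plants[j] for j in np.flatnonzero(n == 0)]
        raise ValidationError(f"plants with no fruits in period {period!r}: {bad}")
    return k, n


def fit_model_suite(
    presence: PresenceMatrix,
    corr: PhyloCorrelation,
    config: RunConfig,
    dataset: Dataset | None = None,
    per_sample: bool = False,
) -> QICTable:
    """Fit the four community-structure models and tabulate their QICs.

    M1  logit p ~ intercept + fly species
    M2  logit p ~ intercept + fly species + plant species
    M3  logit p ~ fly x plant interaction (one mean per cell)
    M4  one GEE per fly species with one parameter per plant, all plants
        in a single cluster whose working correlation is the fixed
        Brownian-motion phylogenetic structure; QIC(M4) is the sum over
        fly species.

    M1-M3 treat plants as clusters with an independence working
    correlation.  By default each (plant, fly) presence cell is one
    binary observation, in which case M3 and M4 are saturated (one
    observation per parameter) and are ridge-stabilized and flagged.
    With ``per_sample=True`` (requires ``dataset``) the response is
    per-fruit presence instead — each (fruit, fly) pair is one binary
    observation, aggregated internally into weighted binomial cells,
    which de-saturates M3/M4 and yields QIC magnitudes that grow with
    the number of fruits sampled.

    Note that M3 and M4 fit the same saturated cell means, so by
    construction QIC — whose quasi-likelihood term is maximized by the
    independence fit and whose sandwich trace vanishes for saturated
    models — cannot favor M4 over M3 by more than ridge-level noise;
    the table reports both so the ordering can be inspected.
    """
    if list(presence.plant_ids) != list(corr.tip_order):
        raise ValidationError("presence matrix and correlation are not aligned")
    plants = presence.plant_ids
    flies = presence.fly_ids
    n_plants, n_flies = len(plants), len(flies)

    if per_sample:
        if dataset is None:
            raise ValidationError("per-fruit mode requires the dataset")
        k, n_fruits = _per_fruit_cells(dataset, presence.period, plants, flies)
        y = (k / n_fruits[:, None]).T.ravel()  # fly-major cell proportions
        weights = np.tile(n_fruits, n_flies)
    else:
        y = presence.values().T.ravel()
        weights = None

    fly_lab = [f for f in flies for _ in plants]
    plant_lab = [p for _ in flies for p in plants]
    n = len(y)
    clusters = np.asarray(plant_lab)
    ones = np.ones((n, 1))
    Xfly = _dummies(fly_lab, flies)
    Xplant = _dummies(plant_lab, plants)

    rows = []

    def _fit_and_row(model_id: str, X: np.ndarray, note: str = "", ridge: float = 0.0):
        fit = fit_gee(
            GEEDesign(
                y=y, X=X, clusters=clusters, working="independence",
                weights=weights,
            ),
            ridge=ridge,
        )
        extra = []
        if fit.separation or fit.ridge > 0:
            extra.append(f"ridge-stabilized (lambda={fit.ridge:.0e})")
        if not fit.converged:
            extra.append("not converged")
        rows.append(
            dict(
                model_id=model_id,
                qic=qic(fit),
                n_params=fit.n_params,
                note="; ".join([note] + extra).strip("; "),
            )
        )
        return fit

    _fit_and_row("M1", np.hstack([ones, Xfly]))
    _fit_and_row("M2", np.hstack([ones, Xfly, Xplant]))
    # M3: one mean per (plant, fly) cell — block-diagonal identity design
    X3 = np.kron(np.eye(n_flies), np.eye(n_plants))
    _fit_and_row(
        "M3",
        X3,
        note="cell means" + ("" if per_sample else " (saturated)"),
        ridge=0.0 if per_sample else DEFAULT_RIDGE,
    )

    # M4: per fly species, one parameter per plant, single phylogenetic cluster
    qic_m4 = 0.0
    m4_params = 0
    m4_notes = {"per-fly phylogenetic GEE, summed QIC"}
    for i, f in enumerate(flies):
        if per_sample:
            yi = (k[:, i] / n_fruits).astype(float)
            wi = n_fruits
        else:
            yi = presence.values()[:, i]
            wi = None
        working = FixedCorrelation(matrix=corr.matrix, positions=np.arange(n_plants))
        fit_i = fit_gee(
            GEEDesign(
                y=yi,
                X=np.eye(n_plants),
                clusters=np.zeros(n_plants, dtype=int),
                working=working,
                weights=wi,
            ),
            ridge=DEFAULT_RIDGE,  # saturated per-plant means
        )
        qic_m4 += qic(fit_i)
        m4_params += fit_i.n_params
        if fit_i.separation or fit_i.ridge > 0:
            m4_notes.add(f"ridge-stabilized (lambda={fit_i.ridge:.0e})")
        if not fit_i.converged:
            m4_notes.add("not converged")
    rows.append(
        dict(
            model_id="M4",
            qic=qic_m4,
            n_params=m4_params,
            note="; ".join(sorted(m4_notes)),
        )
    )

    table = QICTable(rows=pd.DataFrame(rows))
    select_model(table, config)
    return table
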