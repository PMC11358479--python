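"""Environment-suitability (Phi_E) niche model.

Presence/absence records on the model grid are combined with four
standardized bioclim predictors — annual mean temperature ``T_m``,
temperature seasonality ``T_delta``, wettest-month precipitation ``R_m`` and
precipitation seasonality ``R_delta`` — in a second-order (quadratic)
logistic regression:

    q(P) = 1/2 P' A P + B . P + C,      Phi_E = 1 / (1 + exp(-q))

with ``A`` symmetric.  The model is fitted by penalised maximum likelihood
(Newton/IRLS, ridge on A and B only) and validated on held-out splits with
the Brier Skill Score against the intercept-only reference and the area
under the ROC curve.  Uncertainty is carried by an ensemble of refits on
random 80% subsamples; the ensemble-mean Phi_E field is the estimate used
downstream and the ensemble standard deviation its reliability measure.

Presence/absence construction follows spatial-block labelling: blocks
containing at least one site are presences (several sites in one block
collapse to a single record), site-free blocks whose climate violates the
a-priori habitability bounds are absences, and the remaining
pseudo-absence blocks are handled by one of three labelling options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .exceptions import (
    ConfigurationError,
    DegeneratePredictorError,
    FitError,
    UndefinedScoreError,
    UnfittableDataError,
)
from .grid import LandMask, LatLonGrid, ScalarField

logger = logging.getLogger(__name__)

PREDICTOR_NAMES = ("T_m", "T_delta", "R_m", "R_delta")

#: a-priori absence bounds on raw annual mean temperature (degC) and
#: wettest-month precipitation (mm); outside either interval a site-free
#: cell is labelled absent regardless of the other predictors.
APRIORI_T_BOUNDS = (-2.0, 16.0)
APRIORI_R_BOUNDS = (30.0, 250.0)

__all__ = [
    "PREDICTOR_NAMES",
    "SiteCatalog",
    "Standardization",
    "standardize",
    "PresenceAbsenceSet",
    "build_presence_absence",
    "NicheModel",
    "NicheLogistic",
    "NicheFitResults",
    "fit_niche",
    "NicheEnsemble",
    "train_ensemble",
    "brier_score",
    "brier_skill_score",
    "auc",
]


@dataclass
class SiteCatalog:
    """Archaeological site records: id, lon, lat and a phase tag."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "lon", "lat", "phase"}
        missing = required - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"site catalogue missing columns {sorted(missing)}")
        if self.records["id"].duplicated().any():
            raise ConfigurationError("site ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path) -> "SiteCatalog":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass(frozen=True)
class Standardization:
    """Per-predictor mean/s.d. used to standardize training and new inputs."""

    mean: np.ndarray
    std: np.ndarray
    names: tuple[str, ...] = PREDICTOR_NAMES

    def transform(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        return (raw - self.mean) / self.std


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize one predictor: ``(c - mean) / sd``; returns stats for reuse."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise DegeneratePredictorError("predictor has zero variance")
    m = float(values.mean())
    s = float(values.std())
    return (values - m) / s, m, s


@dataclass
class PresenceAbsenceSet:
    """Cell/block-level labelled records with their raw predictor vectors.

    ``cells`` holds one representative ``(ilat, jlon)`` index per record,
    ``x_raw`` the raw predictor matrix (block means), ``labels`` in {0, 1}
    and ``provenance`` in {presence, a-priori-absence, pseudo-absence}.
    Standardization statistics are fitted from these records.
    """

    cells: np.ndarray  # (n, 2) int
    x_raw: np.ndarray  # (n, 4)
    labels: np.ndarray  # (n,) int
    provenance: np.ndarray  # (n,) str
    n_presence: int
    n_pseudo: int
    standardization: Standardization = dfield(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ConfigurationError("labels must be binary")
        seen = set(map(tuple, self.cells.tolist()))
        if len(seen) != len(self.cells):
            raise ConfigurationError("each cell may appear at most once")
        means, stds = [], []
        for k in range(self.x_raw.shape[1]):
            _, m, s = standardize(self.x_raw[:, k])
            means.append(m)
            stds.append(s)
        self.standardization = Standardization(np.array(means), np.array(stds))

    @property
    def x(self) -> np.ndarray:
        """Standardized predictor matrix (training statistics)."""
        return self.standardization.transform(self.x_raw)

    def __len__(self) -> int:
        return len(self.labels)


def _predictor_matrix(fields: dict[str, ScalarField]) -> np.ndarray:
    missing = set(PREDICTOR_NAMES) - set(fields)
    if missing:
        raise ConfigurationError(f"missing predictor fields {sorted(missing)}")
    return np.stack([fields[n].values for n in PREDICTOR_NAMES], axis=-1)


def build_presence_absence(
    sites: SiteCatalog,
    predictor_fields: dict[str, ScalarField],
    grid: LatLonGrid,
    mask: LandMask,
    block_size: float | None = None,
    pseudo_absence_option: int = 3,
    seed: int = 0,
) -> PresenceAbsenceSet:
    """Label spatial blocks as presence / a-priori absence / pseudo-absence.

    Blocks default to single grid cells.  A block containing one or more
    sites yields exactly one presence record (downsampling stacked sites).
    Site-free blocks whose block-mean annual temperature or wettest-month
    precipitation falls outside the a-priori habitability bounds are labelled
    absent.  The remaining pseudo-absence blocks follow the chosen option:

    1. excluded from training;
    2. a random third labelled 0, a third labelled 1, a third excluded;
    3. labelled 1 with probability ``N_p / (N_p + N_pa)``, else 0.

    Predictor vectors are block means over land cells.
    """
    if pseudo_absence_option not in (1, 2, 3):
        raise ConfigurationError("pseudo_absence_option must be 1, 2 or 3")
    block = grid.resolution if block_size is None else float(block_size)
    if block < grid.resolution - 1e-9:
        raise ConfigurationError("block size must be at least the grid resolution")
    rng = np.random.default_rng(seed)
    raw = _predictor_matrix(predictor_fields)

    per_block = max(1, int(round(block / grid.resolution)))
    nbi = -(-grid.nlat // per_block)
    nbj = -(-grid.nlon // per_block)

    # land-cell block membership
    ii, jj = np.nonzero(mask.land)
    bi, bj = ii // per_block, jj // per_block
    block_ids = bi * nbj + bj

    site_blocks: set[int] = set()
    site_cell: dict[int, tuple[int, int]] = {}
    for lon, lat in zip(sites.records["lon"], sites.records["lat"]):
        i, j = grid.locate(lon, lat)
        b = (i // per_block) * nbj + (j // per_block)
        site_blocks.add(b)
        site_cell.setdefault(b, (i, j))

    cells, x_raw, labels, prov = [], [], [], []
    pseudo = []  # (block id, representative cell, predictors)
    for b in np.unique(block_ids):
        members = block_ids == b
        x_mean = raw[ii[members], jj[members]].mean(axis=0)
        rep = (int(ii[members][0]), int(jj[members][0]))
        if b in site_blocks:
            cells.append(site_cell[b])
            x_raw.append(x_mean)
            labels.append(1)
            prov.append("presence")
        else:
            t, r = x_mean[0], x_mean[2]
            if not (APRIORI_T_BOUNDS[0] <= t <= APRIORI_T_BOUNDS[1]) or not (
                APRIORI_R_BOUNDS[0] <= r <= APRIORI_R_BOUNDS[1]
            ):
                cells.append(rep)
                x_raw.append(x_mean)
                labels.append(0)
                prov.append("a-priori-absence")
            else:
                pseudo.append((rep, x_mean))

    n_p = sum(1 for p in prov if p == "presence")
    n_pa = len(pseudo)
    if n_p == 0:
        raise UnfittableDataError("no presence cells; cannot build training data")

    if pseudo_absence_option == 2 and n_pa:
        order = rng.permutation(n_pa)
        third = n_pa // 3
        for k, idx in enumerate(order):
            if k < third:
                lab = 0
            elif k < 2 * third:
                lab = 1
            else:
                continue
            rep, x_mean = pseudo[idx]
            cells.append(rep)
            x_raw.append(x_mean)
            labels.append(lab)
            prov.append("pseudo-absence")
    elif pseudo_absence_option == 3 and n_pa:
        p1 = n_p / (n_p + n_pa)
        draws = rng.random(n_pa) < p1
        for (rep, x_mean), lab in zip(pseudo, draws):
            cells.append(rep)
            x_raw.append(x_mean)
            labels.append(int(lab))
            prov.append("pseudo-absence")

    return PresenceAbsenceSet(
        cells=np.array(cells, dtype=int),
        x_raw=np.array(x_raw, dtype=float),
        labels=np.array(labels, dtype=int),
        provenance=np.array(prov),
        n_presence=n_p,
        n_pseudo=n_pa,
    )


# --------------------------------------------------------------------------
# quadratic-logistic model
# --------------------------------------------------------------------------

_D = len(PREDICTOR_NAMES)
_QUAD_IDX = [(i, j) for i in range(_D) for j in range(i, _D)]
N_COEF = 1 + _D + len(_QUAD_IDX)  # C, B, upper-triangular A


def _design(p_std: np.ndarray) -> np.ndarray:
    """Design matrix [1 | P | quadratic terms] matching the (C, B, A) packing.

    Diagonal quadratic columns carry the 1/2 factor so their coefficients are
    the ``A_ii`` entries directly; off-diagonal columns are ``P_i P_j`` whose
    coefficients are the symmetric ``A_ij``.
    """
    p = np.asarray(p_std, dtype=float)
    if p.ndim != 2 or p.shape[1] != _D:
        raise ValueError(f"predictor matrix must be (n, {_D})")
    cols = [np.ones(len(p)), *(p[:, k] for k in range(_D))]
    for i, j in _QUAD_IDX:
        cols.append(0.5 * p[:, i] ** 2 if i == j else p[:, i] * p[:, j])
    return np.column_stack(cols)


@dataclass(frozen=True)
class NicheModel:
    """Quadratic-logistic suitability model ``Phi_E = expit(q(P))``."""

    A: np.ndarray  # (4, 4) symmetric
    B: np.ndarray  # (4,)
    C: float

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        if A.shape != (_D, _D) or B.shape != (_D,):
            raise ConfigurationError("coefficient dimensions must be 4x4 and 4")
        if np.max(np.abs(A - A.T)) > 1e-12:
            raise ConfigurationError("A must be symmetric")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B)) and np.isfinite(self.C)):
            raise ConfigurationError("coefficients must be finite")

    def q(self, p_std: np.ndarray) -> np.ndarray:
        p = np.asarray(p_std, dtype=float)
        return 0.5 * np.einsum("ni,ij,nj->n", p, self.A, p) + p @ self.B + self.C

    def predict(self, p_std: np.ndarray) -> np.ndarray:
        """Phi_E in (0, 1) for standardized predictor rows."""
        return expit(self.q(p_std))

    def to_vector(self) -> np.ndarray:
        beta = np.empty(N_COEF)
        beta[0] = self.C
        beta[1 : 1 + _D] = self.B
        for k, (i, j) in enumerate(_QUAD_IDX):
            beta[1 + _D + k] = self.A[i, j]
        return beta

    @classmethod
    def from_vector(cls, beta: np.ndarray) -> "NicheModel":
        A = np.zeros((_D, _D))
        for k, (i, j) in enumerate(_QUAD_IDX):
            A[i, j] = A[j, i] = beta[1 + _D + k]
        return cls(A=A, B=np.asarray(beta[1 : 1 + _D], float), C=float(beta[0]))

    def to_dict(self) -> dict:
        return {"A": self.A.tolist(), "B": self.B.tolist(), "C": self.C}

    @classmethod
    def from_dict(cls, d: dict) -> "NicheModel":
        return cls(np.asarray(d["A"], float), np.asarray(d["B"], float), float(d["C"]))


class NicheLogistic:
    """Bernoulli likelihood for the quadratic-logistic suitability model.

    Parameters
    ----------
    endog : (n,) binary labels.
    exog : (n, 4) standardized predictor matrix.
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.ndim != 1 or len(self.endog) != len(self.exog):
            raise ValueError("endog/exog length mismatch")
        if np.unique(self.endog).size < 2:
            raise UnfittableDataError("training labels contain a single class")
        self._X = _design(self.exog)
        # ridge applies to A and B, never to the intercept C
        self._pen = np.ones(N_COEF)
        self._pen[0] = 0.0

    @classmethod
    def from_presence_absence(cls, pa: PresenceAbsenceSet) -> "NicheLogistic":
        return cls(pa.labels, pa.x)

    def _penalized_ll(self, beta: np.ndarray, ridge: float) -> float:
        eta = self._X @ beta
        ll = float(self.endog @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * ridge * float(self._pen @ beta**2)

    def fit(
        self,
        ridge: float = 1e-6,
        tol: float = 1e-8,
        maxiter: int = 200,
    ) -> "NicheFitResults":
        """Penalised ML via Newton/IRLS to gradient-norm tolerance ``tol``."""
        if ridge < 0:
            raise ConfigurationError("ridge must be >= 0")
        X, y = self._X, self.endog
        beta = np.zeros(N_COEF)
        beta[0] = np.log(y.mean() / (1.0 - y.mean()))  # intercept warm start
        ll = self._penalized_ll(beta, ridge)
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            mu = expit(X @ beta)
            grad = X.T @ (y - mu) - ridge * self._pen * beta
            gnorm = float(np.max(np.abs(grad)))
            if gnorm <= tol:
                break
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            H = (X * w[:, None]).T @ X + np.diag(ridge * self._pen + 1e-12)
            step = np.linalg.solve(H, grad)
            # damped Newton: halve until the penalised likelihood improves
            for _ in range(40):
                cand = beta + step
                ll_new = self._penalized_ll(cand, ridge)
                if ll_new >= ll - 1e-12:
                    break
                step = 0.5 * step
            else:
                raise FitError("line search failed", {"iter": n_iter, "gnorm": gnorm})
            beta, ll = cand, ll_new
        else:
            mu = expit(X @ beta)
            grad = X.T @ (y - mu) - ridge * self._pen * beta
            raise FitError(
                "Newton iteration did not converge",
                {"maxiter": maxiter, "gnorm": float(np.max(np.abs(grad)))},
            )
        mu = expit(X @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * w[:, None]).T @ X + np.diag(ridge * self._pen)
        cov = np.linalg.inv(H)
        return NicheFitResults(
            model=self,
            params=NicheModel.from_vector(beta),
            bse=np.sqrt(np.diag(cov)),
            llf=float(y @ (X @ beta) - np.logaddexp(0.0, X @ beta).sum()),
            n_iter=n_iter,
            ridge=ridge,
        )


@dataclass
class NicheFitResults:
    """Fitted coefficients, their standard errors and fit diagnostics."""

    model: NicheLogistic
    params: NicheModel
    bse: np.ndarray  # packed as (C, B, upper-tri A)
    llf: float
    n_iter: int
    ridge: float

    _LABELS = (
        ["C"]
        + [f"B[{n}]" for n in PREDICTOR_NAMES]
        + [f"A[{PREDICTOR_NAMES[i]},{PREDICTOR_NAMES[j]}]" for i, j in _QUAD_IDX]
    )

    def predict(self, p_std: np.ndarray) -> np.ndarray:
        return self.params.predict(p_std)

    def params_vector(self) -> np.ndarray:
        return self.params.to_vector()

    def summary(self) -> str:
        lines = [
            "Quadratic logistic niche model",
            f"  n obs: {len(self.model.endog)}   log-lik: {self.llf:.3f}"
            f"   iterations: {self.n_iter}   ridge: {self.ridge:g}",
            f"  {'term':<22}{'coef':>12}{'std err':>12}",
        ]
        for lab, b, se in zip(self._LABELS, self.params_vector(), self.bse):
            lines.append(f"  {lab:<22}{b:>12.4f}{se:>12.4f}")
        return "\n".join(lines)


def fit_niche(pa: PresenceAbsenceSet, ridge: float = 1e-6) -> NicheModel:
    """Fit the quadratic-logistic model to a presence/absence set."""
    return NicheLogistic.from_presence_absence(pa).fit(ridge=ridge).params


# --------------------------------------------------------------------------
# validation scores
# --------------------------------------------------------------------------


def brier_score(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean squared probability error ``(1/J) sum (H_nj - H_oj)**2``."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must share a length")
    if np.nanmin(predictions) < 0 or np.nanmax(predictions) > 1:
        raise ValueError("predictions must lie in [0, 1]")
    return float(np.mean((predictions - labels) ** 2))


def brier_skill_score(
    member_predictions: list[np.ndarray],
    member_labels: list[np.ndarray],
    reference_predictions: list[np.ndarray],
) -> float:
    """Ensemble Brier Skill Score: ``(1/N) sum_n (1 - BS_n / BS_0n)``.

    The reference is the intercept-only (C-only) model evaluated on the same
    held-out records; 1 marks a perfect ensemble, 0 no skill over the
    reference.
    """
    if not member_predictions:
        raise UndefinedScoreError("no ensemble members")
    total = 0.0
    for pred, lab, ref in zip(member_predictions, member_labels, reference_predictions):
        bs0 = brier_score(ref, lab)
        if bs0 == 0.0:
            raise UndefinedScoreError("reference Brier score is zero")
        total += 1.0 - brier_score(pred, lab) / bs0
    return total / len(member_predictions)


def auc(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties at 1/2)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise UndefinedScoreError("AUC undefined for a single class")
    return float(roc_auc_score(labels, np.asarray(predictions, dtype=float)))


# --------------------------------------------------------------------------
# ensemble training
# --------------------------------------------------------------------------


@dataclass
class NicheEnsemble:
    """Refits of the niche model on random 80% subsamples.

    Carries the member models, their held-out Brier scores (model and
    intercept-only reference) and held-out AUCs; the ensemble-mean Phi_E and
    its standard deviation are evaluated on demand for any standardized
    predictor matrix.
    """

    members: list[NicheModel]
    member_bs: np.ndarray
    member_bs0: np.ndarray
    member_auc: np.ndarray
    standardization: Standardization
    train_fraction: float
    seed: int

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def bss(self) -> float:
        if np.any(self.member_bs0 == 0.0):
            raise UndefinedScoreError("reference Brier score is zero")
        return float(np.mean(1.0 - self.member_bs / self.member_bs0))

    def member_phi(self, p_std: np.ndarray) -> np.ndarray:
        return np.stack([m.predict(p_std) for m in self.members])

    def mean_phi(self, p_std: np.ndarray) -> np.ndarray:
        """Ensemble-mean Phi_E (mean of member fields, stays in [0, 1])."""
        return self.member_phi(p_std).mean(axis=0)

    def std_phi(self, p_std: np.ndarray) -> np.ndarray:
        return self.member_phi(p_std).std(axis=0)

    def predict_fields(
        self, predictor_fields: dict[str, ScalarField], mask: LandMask
    ) -> tuple[ScalarField, ScalarField]:
        """Ensemble mean and s.d. Phi_E fields from raw predictor rasters."""
        raw = _predictor_matrix(predictor_fields)
        flat = raw.reshape(-1, _D)
        p_std = self.standardization.transform(flat)
        if np.any(np.abs(p_std[mask.land.ravel()]) > 5.0):
            logger.info(
                "predictors extend beyond +-5 s.d. of the training range; "
                "the quadratic extrapolates without clamping"
            )
        grid = predictor_fields[PREDICTOR_NAMES[0]].grid
        mean = self.mean_phi(p_std).reshape(grid.shape)
        std = self.std_phi(p_std).reshape(grid.shape)
        return (
            ScalarField(grid, mean, units="1", mask=mask.land.copy()),
            ScalarField(grid, std, units="1", mask=mask.land.copy()),
        )

    def to_dict(self) -> dict:
        return {
            "members": [m.to_dict() for m in self.members],
            "member_bs": self.member_bs.tolist(),
            "member_bs0": self.member_bs0.tolist(),
            "member_auc": self.member_auc.tolist(),
            "standardization": {
                "mean": self.standardization.mean.tolist(),
                "std": self.standardization.std.tolist(),
            },
            "train_fraction": self.train_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NicheEnsemble":
        return cls(
            members=[NicheModel.from_dict(m) for m in d["members"]],
            member_bs=np.asarray(d["member_bs"], float),
            member_bs0=np.asarray(d["member_bs0"], float),
            member_auc=np.asarray(d["member_auc"], float),
            standardization=Standardization(
                np.asarray(d["standardization"]["mean"], float),
                np.asarray(d["standardization"]["std"], float),
            ),
            train_fraction=float(d["train_fraction"]),
            seed=int(d["seed"]),
        )

    def summary(self) -> str:
        return (
            f"Niche ensemble: {self.n_members} members, "
            f"BSS={self.bss:.3f}, held-out AUC={self.member_auc.mean():.3f} "
            f"(member s.d. {self.member_auc.std():.3f})"
        )


def train_ensemble(
    pa: PresenceAbsenceSet,
    n_members: int = 1000,
    train_fraction: float = 0.8,
    seed: int = 0,
    ridge: float = 1e-6,
) -> NicheEnsemble:
    """Train ``n_members`` refits, each on a random 80% of the records.

    Every member is scored on its own held-out 20% (Brier score, reference
    intercept-only Brier score, AUC).  Splits leaving either part with a
    single class are redrawn; more than 100 failures raise an error.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    if n_members < 1:
        raise ConfigurationError("n_members must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(pa)
    n_train = int(round(train_fraction * n))
    if not 0 < n_train < n:
        raise UnfittableDataError("too few records for the requested split")
    y = pa.labels
    x = pa.x

    members, bs, bs0, aucs = [], [], [], []
    for _ in range(n_members):
        for attempt in range(101):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if np.unique(y[tr]).size == 2 and np.unique(y[te]).size == 2:
                break
        else:
            raise UnfittableDataError("could not draw a split with both classes")
        res = NicheLogistic(y[tr], x[tr]).fit(ridge=ridge)
        pred = res.predict(x[te])
        # intercept-only reference refitted on the same training subset
        p_ref = float(y[tr].mean())
        members.append(res.params)
        bs.append(brier_score(pred, y[te]))
        bs0.append(brier_score(np.full(len(te), p_ref), y[te]))
        aucs.append(auc(pred, y[te]))

    return NicheEnsemble(
        members=members,
        member_bs=np.asarray(bs),
        member_bs0=np.asarray(bs0),
        member_auc=np.asarray(aucs),
        standardization=pa.standardization,
        train_fraction=train_fraction,
        seed=seed,
    )
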