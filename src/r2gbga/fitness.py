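"""Objective functions for the GA.

Three kinds of fitness are provided:

* rediscovery: Tanimoto similarity of the candidate's ECFP4 fingerprint
  to a fixed target structure (1.0 iff the fingerprints are identical);
* property targeting: a Gaussian-process-regression surrogate with a
  Tanimoto kernel over fingerprints predicts a scalar property (an
  excitation energy in eV, an IC50 in nM, ...) and the score is
  ``-|prediction - target|``, maximal when the prediction hits the
  target value;
* synthetic feasibility: the Ertl fragment-contribution synthetic
  accessibility score (SAScore, 1 easy - 10 hard) computed natively,
  plus adapters for external learned scorers (SYBA, RAscore) whose
  trained models are user-supplied.

The GP is exact: with a positive-semidefinite Tanimoto kernel, zero
observation noise and a numerical jitter, the posterior mean
interpolates the training data. The prior mean is the training-set mean.
"""

from __future__ import annotations

import logging
import math
import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize_scalar

from .chemcore import (
    DEFAULT_FP_PARAMS,
    Fingerprint,
    FingerprintParams,
    Molecule,
    fingerprint_matrix,
    tanimoto,
    tanimoto_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GPRModel",
    "gpr_fit",
    "gpr_predict",
    "optimize_signal_variance",
    "Objective",
    "rediscovery_score",
    "sa_score",
    "sa_score_available",
    "register_scorer",
    "external_score",
    "FeasibilityReport",
    "feasibility_report",
]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6, 1e-4)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return np.asarray(X, dtype=np.float64)
    rows = []
    for x in X:
        rows.append(x.bits if isinstance(x, Fingerprint) else np.asarray(x))
    return np.asarray(np.stack(rows), dtype=np.float64)


class GPRModel:
    """Exact GP regression with a Tanimoto (binary MinMax) kernel.

    k(x, x') = signal_variance * T(x, x'), where T is the Tanimoto
    similarity of the two binary fingerprints. Fitting factorizes the
    Gram matrix by Cholesky decomposition, escalating a diagonal jitter
    until the factorization succeeds; failure at the largest jitter is
    fatal and reports the condition number.
    """

    def __init__(self, signal_variance: float = 1.0, noise: float = 1e-6):
        if signal_variance <= 0:
            raise ValueError("signal_variance must be > 0")
        if noise < 0:
            raise ValueError("noise must be >= 0")
        self.signal_variance = float(signal_variance)
        self.noise = float(noise)
        self._X: Optional[np.ndarray] = None
        self._y_mean = 0.0
        self._alpha: Optional[np.ndarray] = None
        self._L: Optional[np.ndarray] = None
        self._resid: Optional[np.ndarray] = None
        self.jitter_used: float = 0.0

    @property
    def fitted(self) -> bool:
        return self._alpha is not None

    def fit(self, X, y) -> "GPRModel":
        X = _as_matrix(X)
        y = np.asarray(y, dtype=np.float64)
        if X.shape[0] != y.shape[0] or y.shape[0] < 1:
            raise ValueError("need equally many fingerprints and values, at least 1")
        if not np.all(np.isfinite(y)):
            raise ValueError("training values must be finite")
        K = self.signal_variance * tanimoto_matrix(X)
        n = K.shape[0]
        last_err = None
        for jitter in _JITTERS:
            try:
                self._L = np.linalg.cholesky(
                    K + (self.noise + jitter) * np.eye(n)
                )
                self.jitter_used = jitter
                break
            except np.linalg.LinAlgError as err:
                last_err = err
                self._L = None
        if self._L is None:
            cond = np.linalg.cond(K)
            raise np.linalg.LinAlgError(
                f"Gram matrix not positive definite even with jitter "
                f"{_JITTERS[-1]:g} (condition number {cond:.3e})"
            ) from last_err
        self._X = X
        self._y_mean = float(y.mean())
        self._resid = y - self._y_mean
        self._alpha = cho_solve((self._L, True), self._resid)
        return self

    def predict(self, query) -> Tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation at the query points.

        A query with zero kernel similarity to every training point gets
        the prior back: mean = training mean, std = sqrt(signal_variance).
        """
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        single = isinstance(query, Fingerprint) or (
            isinstance(query, np.ndarray) and query.ndim == 1
        )
        Q = _as_matrix([query] if single else query)
        Ks = self.signal_variance * tanimoto_matrix(Q, self._X)
        mean = self._y_mean + Ks @ self._alpha
        V = solve_triangular(self._L, Ks.T, lower=True)
        var = self.signal_variance - np.einsum("ij,ij->j", V, V)
        std = np.sqrt(np.clip(var, 0.0, None))
        if single:
            return float(mean[0]), float(std[0])
        return mean, std

    def log_marginal_likelihood(self) -> float:
        """-1/2 r^T K^-1 r - sum log diag(L) - n/2 log 2pi, r = y - mean."""
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        n = self._X.shape[0]
        return float(
            -0.5 * self._resid @ self._alpha
            - np.log(np.diag(self._L)).sum()
            - 0.5 * n * math.log(2 * math.pi)
        )

    def __getstate__(self):
        return self.__dict__

    def __setstate__(self, state):
        self.__dict__.update(state)


def _log_marginal_likelihood(X: np.ndarray, y: np.ndarray,
                             signal_variance: float, noise: float) -> float:
    K = signal_variance * tanimoto_matrix(X)
    n = K.shape[0]
    for jitter in _JITTERS:
        try:
            L = np.linalg.cholesky(K + (noise + jitter) * np.eye(n))
            break
        except np.linalg.LinAlgError:
            L = None
    if L is None:
        return -np.inf
    resid = y - y.mean()
    alpha = cho_solve((L, True), resid)
    return float(
        -0.5 * resid @ alpha
        - np.log(np.diag(L)).sum()
        - 0.5 * n * math.log(2 * math.pi)
    )


def gpr_fit(X, y, noise: float = 1e-6, signal_variance: float = 1.0) -> GPRModel:
    """Fit an exact Tanimoto-kernel GP to fingerprints and values."""
    return GPRModel(signal_variance=signal_variance, noise=noise).fit(X, y)


def gpr_predict(model: GPRModel, query) -> Tuple[float, float]:
    """Posterior (mean, std) at one query fingerprint."""
    return model.predict(query)


def optimize_signal_variance(
    X, y, noise: float = 1e-6, bounds: Tuple[float, float] = (1e-3, 1e3)
) -> float:
    """Maximize the GP marginal likelihood over the signal variance.

    One-dimensional search on log sigma_f^2; used for hyperparameter
    recovery checks and as a pragmatic default when no variance is known.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)

    def neg_lml(log_sf2: float) -> float:
        return -_log_marginal_likelihood(X, y, math.exp(log_sf2), noise)

    res = minimize_scalar(
        neg_lml,
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
    )
    return float(math.exp(res.x))


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def rediscovery_score(
    candidate: Molecule,
    target: Molecule,
    params: FingerprintParams = DEFAULT_FP_PARAMS,
) -> float:
    """Tanimoto similarity of the ECFP4 fingerprints; 1.0 iff identical."""
    return tanimoto(candidate.fingerprint(params), target.fingerprint(params))


@dataclass
class Objective:
    """A callable fitness functional.

    ``maximize_similarity`` scores a candidate by its Tanimoto similarity
    to a target structure (the rediscovery objective, bounded in [0,1]).
    ``target_value`` scores by ``-|prediction - target|`` using the GP
    surrogate, maximal exactly when the prediction equals the target.
    For IC50-like targets spanning orders of magnitude, ``log10_scale``
    models values (and the target) on the log10 scale internally.
    """

    mode: str
    target: Union[float, Molecule]
    model: Optional[GPRModel] = None
    log10_scale: bool = False
    params: FingerprintParams = DEFAULT_FP_PARAMS

    def __post_init__(self):
        if self.mode not in ("maximize_similarity", "target_value"):
            raise ValueError(f"unknown objective mode {self.mode!r}")
        if self.mode == "maximize_similarity" and not isinstance(self.target, Molecule):
            raise ValueError("maximize_similarity needs a Molecule target")
        if self.mode == "target_value":
            if self.model is None or not self.model.fitted:
                raise ValueError("target_value needs a fitted GPRModel")
            self._target_internal = (
                math.log10(float(self.target)) if self.log10_scale else float(self.target)
            )

    def __call__(self, mol: Molecule) -> float:
        if self.mode == "maximize_similarity":
            return rediscovery_score(mol, self.target, self.params)
        mean, _ = self.model.predict(mol.fingerprint(self.params))
        return -abs(mean - self._target_internal)

    @classmethod
    def from_training_data(
        cls,
        molecules: Sequence[Molecule],
        values: Sequence[float],
        target: float,
        noise: float = 1e-6,
        signal_variance: float = 1.0,
        log10_scale: bool = False,
        params: FingerprintParams = DEFAULT_FP_PARAMS,
    ) -> "Objective":
        """Fit the GP surrogate on (molecule, value) pairs, then target a value."""
        y = np.asarray(values, dtype=np.float64)
        if log10_scale:
            if np.any(y <= 0):
                raise ValueError("log10 scale requires strictly positive values")
            y = np.log10(y)
        X = fingerprint_matrix(list(molecules), params)
        model = gpr_fit(X, y, noise=noise, signal_variance=signal_variance)
        return cls(
            mode="target_value",
            target=target,
            model=model,
            log10_scale=log10_scale,
            params=params,
        )


# ---------------------------------------------------------------------------
# synthetic-accessibility scoring
# ---------------------------------------------------------------------------

_SASCORER = None
_SASCORER_FAILED = False


def _load_sascorer():
    """The Ertl fragment-contribution scorer shipped in RDKit's Contrib tree."""
    global _SASCORER, _SASCORER_FAILED
    if _SASCORER is not None or _SASCORER_FAILED:
        return _SASCORER
    try:
        from rdkit.Chem import RDConfig

        sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if sa_dir not in sys.path:
            sys.path.append(sa_dir)
        import sascorer  # noqa: F401

        _SASCORER = sascorer
    except Exception as exc:  # missing fragment-score resource
        logger.warning("SAScore unavailable: %s", exc)
        _SASCORER_FAILED = True
    return _SASCORER


def sa_score_available() -> bool:
    return _load_sascorer() is not None


def sa_score(mol: Molecule) -> float:
    """Ertl synthetic-accessibility score, nominally 1 (easy) to 10 (hard).

    Combines fragment-frequency contributions with complexity penalties
    (rings, stereocenters, macrocycles, size). Raises RuntimeError if the
    fragment-score table cannot be loaded; callers that can degrade
    should check :func:`sa_score_available` first.
    """
    scorer = _load_sascorer()
    if scorer is None:
        raise RuntimeError("SAScore fragment-score resource unavailable")
    return float(scorer.calculateScore(mol.mol))


# ---------------------------------------------------------------------------
# external (pluggable) feasibility scorers
# ---------------------------------------------------------------------------

MISSING = None  # marker for a per-molecule scorer failure

_SCORER_REGISTRY: Dict[str, Callable[[List[str]], List[Optional[float]]]] = {}


def register_scorer(name: str, hook: Callable[[List[str]], List[Optional[float]]]) -> None:
    """Register an external scorer (e.g. SYBA, RAscore).

    The hook receives a list of SMILES and returns one value per input
    (None for per-molecule failures). Trained models are the user's to
    supply; nothing is bundled.
    """
    _SCORER_REGISTRY[name] = hook


def unregister_scorer(name: str) -> None:
    _SCORER_REGISTRY.pop(name, None)


def registered_scorers() -> List[str]:
    return sorted(_SCORER_REGISTRY)


def external_score(
    mols: Sequence[Molecule],
    scorer_name: str,
    hook: Optional[Callable[[List[str]], List[Optional[float]]]] = None,
) -> Dict[str, Optional[float]]:
    """Run one external scorer over molecules; SMILES-keyed results.

    Per-molecule failures are explicit None markers; a scorer that
    crashes outright yields all-None with a warning rather than failing
    the run.
    """
    fn = hook if hook is not None else _SCORER_REGISTRY.get(scorer_name)
    if fn is None:
        raise KeyError(f"no scorer registered under {scorer_name!r}")
    smiles = [m.smiles for m in mols]
    try:
        values = list(fn(smiles))
        if len(values) != len(smiles):
            raise ValueError(
                f"scorer {scorer_name!r} returned {len(values)} values for "
                f"{len(smiles)} molecules"
            )
    except Exception as exc:
        logger.warning("external scorer %r failed: %s", scorer_name, exc)
        values = [MISSING] * len(smiles)
    out = {}
    for s, v in zip(smiles, values):
        out[s] = float(v) if v is not None and np.isfinite(v) else MISSING
    return out


@dataclass
class FeasibilityReport:
    """Per-molecule synthetic-feasibility scores.

    ``sa`` holds the native SAScore per SMILES (absent entirely when the
    fragment table is unavailable); ``external`` maps scorer name ->
    SMILES -> value-or-None.
    """

    smiles: List[str]
    sa: Optional[Dict[str, float]] = None
    external: Dict[str, Dict[str, Optional[float]]] = field(default_factory=dict)

    def to_tsv(self) -> str:
        scorers = sorted(self.external)
        header = ["smiles"] + (["sa_score"] if self.sa is not None else []) + scorers
        lines = ["\t".join(header)]
        for s in self.smiles:
            row = [s]
            if self.sa is not None:
                row.append(f"{self.sa[s]:.4f}")
            for name in scorers:
                v = self.external[name].get(s)
                row.append("NA" if v is None else f"{v:.4f}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def mean_sa(self) -> Optional[float]:
        if not self.sa:
            return None
        return float(np.mean(list(self.sa.values())))


def feasibility_report(
    mols: Sequence[Molecule],
    external_scorers: Sequence[str] = (),
) -> FeasibilityReport:
    """Score molecules with SAScore plus any registered external scorers."""
    smiles = [m.smiles for m in mols]
    sa = None
    if sa_score_available():
        sa = {m.smiles: sa_score(m) for m in mols}
    report = FeasibilityReport(smiles=smiles, sa=sa)
    for name in external_scorers:
        report.external[name] = external_score(mols, name)
    return report
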