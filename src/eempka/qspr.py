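"""QSPR model fitting, diagnostics and validation.

The pKa of a molecule is modelled as a linear combination of the charge
descriptors of its dissociation site, fitted by ordinary least squares:

    3d (phenols):  pKa = p_H q_H + p_O q_O + p_C1 q_C1 + p
    5d (phenols):  ... + p'_OD q_OD + p'_C1D q_C1D
    4d (acids):    pKa = p_H q_H + p_O q_O + p_O2 q_O2 + p_C1 q_C1 + p
    7d (acids):    ... + p'_OD q_OD + p'_O2D q_O2D + p'_C1D q_C1D

Model quality is reported as the squared Pearson correlation between
predicted and experimental pKa (R^2), RMSE = sqrt(SSE/n), the mean absolute
error, the residual standard deviation s = sqrt(SSE/(n-k-1)) and the overall
regression F statistic.  Influence screening ranks observations by Cook's
distance and refits after excluding the top 10%; robustness is checked by
pKa-stratified 5-fold cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import (
    CollinearityError,
    DegenerateFoldError,
    DegenerateLeverageError,
    DescriptorError,
    JoinError,
)

KIND_SYMBOLS: dict[str, tuple[str, ...]] = {
    "3d": ("q_H", "q_O", "q_C1"),
    "5d": ("q_H", "q_O", "q_C1", "q_OD", "q_C1D"),
    "4d": ("q_H", "q_O", "q_O2", "q_C1"),
    "7d": ("q_H", "q_O", "q_O2", "q_C1", "q_OD", "q_O2D", "q_C1D"),
}


@dataclass(frozen=True)
class QsprModel:
    kind: str
    descriptor_symbols: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    charge_scheme: str = ""
    training_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in KIND_SYMBOLS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.descriptor_symbols != KIND_SYMBOLS[self.kind]:
            raise ValueError(
                f"kind {self.kind!r} requires symbols {KIND_SYMBOLS[self.kind]}, "
                f"got {self.descriptor_symbols}"
            )
        if len(self.coefficients) != len(self.descriptor_symbols):
            raise ValueError("one coefficient per descriptor symbol required")

    @property
    def k(self) -> int:
        return len(self.descriptor_symbols)


@dataclass(frozen=True)
class FitReport:
    r2: float
    rmse: float
    mae: float
    s: float
    f_stat: float
    n: int
    k: int


@dataclass(frozen=True)
class OutlierReport:
    outlier_ids: tuple[str, ...]
    cooks: pd.Series
    full_model: QsprModel
    full_report: FitReport
    refit_model: QsprModel
    refit: FitReport


@dataclass(frozen=True)
class FoldResult:
    fold: int
    train_report: FitReport
    test_report: FitReport
    model: QsprModel
    test_ids: tuple[str, ...]


@dataclass(frozen=True)
class CvReport:
    folds: tuple[FoldResult, ...]
    assignment: dict[str, int]
    seed: int = 0
    k_folds: int = 5


# ---------------------------------------------------------------------------


def _join(descriptors: pd.DataFrame, pka: pd.DataFrame, kind: str) -> pd.DataFrame:
    symbols = KIND_SYMBOLS[kind]
    missing = [s for s in symbols if s not in descriptors.columns]
    if missing:
        raise DescriptorError(
            f"descriptor table lacks columns {missing} required by kind {kind!r}"
        )
    merged = descriptors.merge(
        pka[["molecule_id", "pka_exp"]], on="molecule_id", how="inner"
    )
    if len(merged) != len(descriptors) or len(merged) != len(pka):
        raise JoinError(
            f"molecule ids do not align: {len(descriptors)} descriptor rows, "
            f"{len(pka)} pKa rows, {len(merged)} in common"
        )
    return merged.sort_values("molecule_id", kind="stable").reset_index(drop=True)


def _design(merged: pd.DataFrame, kind: str):
    symbols = KIND_SYMBOLS[kind]
    X = merged[list(symbols)].to_numpy(dtype=float)
    y = merged["pka_exp"].to_numpy(dtype=float)
    ids = merged["molecule_id"].tolist()
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise CollinearityError(
            f"design matrix for kind {kind!r} is rank-deficient "
            "(collinear or zero-variance descriptor columns)"
        )
    return Xc, y, ids


def _pearson_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def _report(pred: np.ndarray, obs: np.ndarray, k: int) -> FitReport:
    n = len(obs)
    resid = obs - pred
    sse = float(resid @ resid)
    ssr = float(((pred - obs.mean()) ** 2).sum())
    dof = n - k - 1
    s = math.sqrt(sse / dof) if dof > 0 else float("nan")
    if dof > 0 and sse > 0:
        f_stat = (ssr / k) / (sse / dof)
    else:
        f_stat = float("inf") if dof > 0 else float("nan")
    return FitReport(
        r2=_pearson_r2(pred, obs),
        rmse=math.sqrt(sse / n),
        mae=float(np.abs(resid).mean()),
        s=s,
        f_stat=f_stat,
        n=n,
        k=k,
    )


def fit_mlr(
    descriptors: pd.DataFrame,
    pka: pd.DataFrame,
    kind: str,
    charge_scheme: str = "",
) -> tuple[QsprModel, FitReport]:
    """Fit the OLS model of the given kind and report training-set quality.

    Requires n > k + 1 and a full-rank design; ids must match one-to-one
    between the descriptor and pKa tables.
    """
    merged = _join(descriptors, pka, kind)
    symbols = KIND_SYMBOLS[kind]
    k = len(symbols)
    if len(merged) <= k + 1:
        raise ValueError(
            f"need more than {k + 1} molecules to fit a {kind} model, "
            f"got {len(merged)}"
        )
    Xc, y, ids = _design(merged, kind)
    res = sm.OLS(y, Xc).fit()
    model = QsprModel(
        kind=kind,
        descriptor_symbols=symbols,
        coefficients=tuple(float(c) for c in res.params[1:]),
        intercept=float(res.params[0]),
        charge_scheme=charge_scheme,
        training_ids=tuple(ids),
    )
    return model, _report(np.asarray(res.fittedvalues), y, k)


def predict(model: QsprModel, record) -> float | np.ndarray:
    """Apply the fitted model: dot product of descriptors plus intercept.

    ``record`` may be a mapping, a Series, or a DataFrame (vectorized).
    """
    if isinstance(record, pd.DataFrame):
        missing = [s for s in model.descriptor_symbols if s not in record.columns]
        if missing:
            raise DescriptorError(f"record lacks descriptors {missing}")
        X = record[list(model.descriptor_symbols)].to_numpy(dtype=float)
        return X @ np.asarray(model.coefficients) + model.intercept
    try:
        values = [float(record[s]) for s in model.descriptor_symbols]
    except (KeyError, IndexError) as exc:
        raise DescriptorError(
            f"record lacks descriptor {exc} required by {model.kind} model"
        ) from exc
    return float(np.dot(values, model.coefficients) + model.intercept)


def evaluate(model: QsprModel, descriptors: pd.DataFrame, pka: pd.DataFrame) -> FitReport:
    """Quality report of an already-fitted model on a (possibly held-out) set."""
    merged = _join(descriptors, pka, model.kind)
    pred = predict(model, merged)
    return _report(pred, merged["pka_exp"].to_numpy(dtype=float), model.k)


def cooks_distances(
    descriptors: pd.DataFrame, pka: pd.DataFrame, kind: str
) -> pd.Series:
    """Cook's distance D_i of every observation under the OLS fit.

    D_i = e_i^2 / (m s^2) * h_ii / (1 - h_ii)^2 with m = k + 1 fitted
    parameters, e_i the raw residual and h_ii the leverage.  Returned as a
    Series indexed by molecule_id.
    """
    merged = _join(descriptors, pka, kind)
    Xc, y, ids = _design(merged, kind)
    res = sm.OLS(y, Xc).fit()
    leverage = OLSInfluence(res).hat_matrix_diag
    if np.any(leverage >= 1.0 - 1e-12):
        idx = int(np.argmax(leverage))
        raise DegenerateLeverageError(
            f"observation {ids[idx]!r} has leverage 1 (exactly determining)"
        )
    d = OLSInfluence(res).cooks_distance[0]
    return pd.Series(d, index=pd.Index(ids, name="molecule_id"), name="cooks_d")


def remove_outliers_and_refit(
    descriptors: pd.DataFrame,
    pka: pd.DataFrame,
    kind: str,
    fraction: float = 0.10,
    charge_scheme: str = "",
) -> OutlierReport:
    """Exclude the top ``fraction`` of molecules by Cook's distance and refit.

    floor(fraction * n) molecules are dropped (74 molecules at the default
    10% -> 7 dropped, 67 retained); ties in D are broken by molecule_id
    ascending.  The refit is evaluated on the reduced set only.
    """
    full_model, full_report = fit_mlr(descriptors, pka, kind, charge_scheme)
    d = cooks_distances(descriptors, pka, kind)
    n_drop = int(math.floor(fraction * len(d)))
    ranked = d.reset_index().sort_values(
        ["cooks_d", "molecule_id"], ascending=[False, True], kind="stable"
    )
    outliers = tuple(ranked["molecule_id"].iloc[:n_drop])
    keep = ~descriptors["molecule_id"].isin(outliers)
    keep_pka = ~pka["molecule_id"].isin(outliers)
    if n_drop == 0:
        refit_model, refit_report = full_model, full_report
    else:
        refit_model, refit_report = fit_mlr(
            descriptors[keep], pka[keep_pka], kind, charge_scheme
        )
    return OutlierReport(
        outlier_ids=outliers,
        cooks=d,
        full_model=full_model,
        full_report=full_report,
        refit_model=refit_model,
        refit=refit_report,
    )


def assign_stratified_folds(
    pka: pd.DataFrame, k_folds: int, seed: int
) -> dict[str, int]:
    """pKa-stratified random fold assignment.

    Molecules are sorted by experimental pKa (ties by id), cut into
    consecutive blocks of ``k_folds``, and each block's members are randomly
    dealt one per fold, so every fold spans the whole pKa range and fold
    sizes differ by at most one.
    """
    rng = np.random.default_rng(seed)
    ordered = pka.sort_values(
        ["pka_exp", "molecule_id"], kind="stable"
    )["molecule_id"].tolist()
    assignment: dict[str, int] = {}
    for start in range(0, len(ordered), k_folds):
        block = ordered[start : start + k_folds]
        folds = rng.permutation(k_folds)[: len(block)]
        for mol_id, f in zip(block, folds):
            assignment[mol_id] = int(f)
    return assignment


def cross_validate(
    descriptors: pd.DataFrame,
    pka: pd.DataFrame,
    kind: str,
    k_folds: int = 5,
    seed: int = 0,
    charge_scheme: str = "",
) -> CvReport:
    """Stratified k-fold cross-validation with full quality reports per fold.

    Each round trains on k-1 folds and evaluates on the held-out fold; the
    held-out R^2 is the squared Pearson correlation of predicted vs
    experimental pKa (not forced equal to 1 - SSE/SST out of sample).
    """
    merged = _join(descriptors, pka, kind)
    if len(merged) < 2 * k_folds:
        raise DegenerateFoldError(
            f"{len(merged)} molecules cannot support {k_folds} folds of >= 2"
        )
    assignment = assign_stratified_folds(merged, k_folds, seed)
    folds = []
    for f in range(k_folds):
        test_ids = {m for m, ff in assignment.items() if ff == f}
        if len(test_ids) < 2:
            raise DegenerateFoldError(f"fold {f} has {len(test_ids)} members")
        test_mask = merged["molecule_id"].isin(test_ids)
        train = merged[~test_mask]
        test = merged[test_mask]
        model, train_report = fit_mlr(
            train.drop(columns="pka_exp"),
            train[["molecule_id", "pka_exp"]],
            kind,
            charge_scheme,
        )
        test_report = evaluate(
            model, test.drop(columns="pka_exp"), test[["molecule_id", "pka_exp"]]
        )
        folds.append(
            FoldResult(
                fold=f,
                train_report=train_report,
                test_report=test_report,
                model=model,
                test_ids=tuple(sorted(test_ids)),
            )
        )
    return CvReport(
        folds=tuple(folds), assignment=assignment, seed=seed, k_folds=k_folds
    )
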