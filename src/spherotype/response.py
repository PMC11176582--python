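"""Treatment-response scoring in PCA space.

Workflow: standardize the viability metrics table (each column to mean 0,
SD 1, pooled over all cell lines, days and concentrations), run a
two-component PCA, drop every variable whose largest absolute loading on
those two components is below a threshold (0.5 by default), refit on the
survivors, average the scores per (cell line, day, concentration) group,
and express response as the Euclidean distance of each treatment group's
mean from its same-line, same-day control mean.  Distances are classed
low / intermediate / high by the lower and upper quartiles of the pooled
treatment-distance distribution (linear-interpolation quantiles).

Loadings are the correlation-scaled form (unit-norm eigenvectors times the
square root of their eigenvalues), the convention under which individual
variables can reach loadings near 1 and a 0.5 filter is meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vmetrics import PCA_VARIABLES

__all__ = [
    "ANNOTATION_COLUMNS",
    "ScalingRecord",
    "PCAModel",
    "validate_metrics_table",
    "standardize",
    "fit_filtered_pca",
    "fit_response_model",
    "group_distances",
    "quartile_thresholds",
    "classify_distances",
    "classify_responses",
]

ANNOTATION_COLUMNS = ("cell_line", "day", "concentration_ug_ml", "replicate")


@dataclass(frozen=True)
class ScalingRecord:
    variables: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray  # sample SD (ddof=1)


def validate_metrics_table(table: pd.DataFrame,
                           variables: tuple[str, ...] = PCA_VARIABLES) -> None:
    missing = [c for c in ("cell_line", "day", "concentration_ug_ml") if c not in table]
    if missing:
        raise ValueError(f"metrics table missing annotation columns: {missing}")
    missing = [v for v in variables if v not in table]
    if missing:
        raise ValueError(f"metrics table missing variables: {missing}")
    if table[list(variables)].isna().any().any():
        raise ValueError("metrics table contains missing values")
    for (line, day), grp in table.groupby(["cell_line", "day"]):
        if not (grp["concentration_ug_ml"] == 0).any():
            raise ValueError(f"no concentration-0 control for ({line}, day {day})")


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, ScalingRecord]:
    """Scale every column to mean 0 and (sample) SD 1, pooled across all
    rows.  A constant column is rejected by name."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    X = table.astype(float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = sds.index[sds == 0].tolist()
    if dead:
        raise ValueError(f"constant column(s) cannot be standardized: {dead}")
    scaled = (X - means) / sds
    return scaled, ScalingRecord(tuple(X.columns), means.to_numpy(), sds.to_numpy())


def _pca_correlation(scaled: np.ndarray, n_components: int = 2):
    """Eigendecomposition of the sample correlation matrix of standardized
    data.  Returns (components, eigenvalues, loadings, explained) with
    components the unit-norm eigenvectors sorted by descending eigenvalue,
    each retained component oriented so its largest-|loading| variable has
    a positive loading."""
    corr = np.cov(scaled, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(min(n_components, eigvecs.shape[1])):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    loadings = eigvecs[:, :n_components] * np.sqrt(eigvals[:n_components])
    explained = eigvals / eigvals.sum() if eigvals.sum() > 0 else eigvals
    return eigvecs, eigvals, loadings, explained


@dataclass
class PCAModel:
    """Fitted 2-component PCA over the surviving variables.

    ``components`` holds unit-norm eigenvector columns; ``loadings`` the
    correlation-scaled loadings used by the filter.  ``means``/``sds`` map
    raw variable values into the standardized space the model was fit in.
    """

    variable_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    components: np.ndarray        # (p, 2), unit-norm columns
    eigenvalues: np.ndarray       # all p, descending
    loadings: np.ndarray          # (p, 2)
    explained_variance: np.ndarray
    loading_threshold: float = 0.5
    excluded: tuple[str, ...] = ()
    n_components: int = 2
    stage1_loadings: dict = field(default_factory=dict)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.variable_names)].to_numpy(dtype=float)
        Z = (X - self.means) / self.sds
        return Z @ self.components[:, : self.n_components]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "variable_names": list(self.variable_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "components": self.components[:, : self.n_components].tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "loading_threshold": self.loading_threshold,
            "excluded": list(self.excluded),
            "n_components": self.n_components,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_filtered_pca(scaled: pd.DataFrame, loading_threshold: float = 0.5
                     ) -> tuple[PCAModel, list[str]]:
    """Two-stage PCA on a standardized matrix.

    Stage 1 fits all variables and keeps the two largest-eigenvalue
    components; any variable whose maximum |loading| on them is below
    ``loading_threshold`` is excluded.  Stage 2 re-standardizes the
    survivors and refits.  Returns the final model and the excluded list.
    """
    if scaled.shape[1] < 3:
        raise ValueError("need at least 3 variables")
    names = list(scaled.columns)
    _, _, load1, _ = _pca_correlation(scaled.to_numpy(dtype=float))
    strength = np.abs(load1).max(axis=1)
    excluded = [n for n, s in zip(names, strength) if s < loading_threshold]
    survivors = [n for n in names if n not in excluded]
    if len(survivors) < 3:
        raise ValueError(
            f"loading filter left {len(survivors)} variable(s); need >= 3"
        )
    rescaled, scaling = standardize(scaled[survivors])
    comps, eigvals, loadings, explained = _pca_correlation(
        rescaled.to_numpy(dtype=float)
    )
    model = PCAModel(
        variable_names=tuple(survivors),
        means=scaling.means,
        sds=scaling.sds,
        components=comps,
        eigenvalues=eigvals,
        loadings=loadings,
        explained_variance=explained,
        loading_threshold=loading_threshold,
        excluded=tuple(excluded),
        stage1_loadings={n: load1[i].tolist() for i, n in enumerate(names)},
    )
    return model, excluded


def fit_response_model(table: pd.DataFrame,
                       variables: tuple[str, ...] = PCA_VARIABLES,
                       loading_threshold: float = 0.5) -> PCAModel:
    """Standardize an annotated metrics table and fit the filtered PCA,
    recording raw-scale means/SDs so the model can score raw data."""
    validate_metrics_table(table, variables)
    scaled, scaling = standardize(table[list(variables)])
    model, _ = fit_filtered_pca(scaled, loading_threshold)
    # compose the two scalings so transform() accepts raw metric values
    idx = [scaling.variables.index(v) for v in model.variable_names]
    raw_means = scaling.means[idx]
    raw_sds = scaling.sds[idx]
    # scaled = (raw - m1)/s1; rescaled = (scaled - m2)/s2
    model.means = raw_means + model.means * raw_sds
    model.sds = model.sds * raw_sds
    return model


def group_distances(model: PCAModel, table: pd.DataFrame) -> pd.DataFrame:
    """Mean (PC1, PC2) per (cell_line, day, concentration) and Euclidean
    distance of each treatment mean from its same-line, same-day control
    mean."""
    scores = model.transform(table)
    df = table[["cell_line", "day", "concentration_ug_ml"]].copy()
    df["pc1"] = scores[:, 0]
    df["pc2"] = scores[:, 1]
    grouped = (
        df.groupby(["cell_line", "day", "concentration_ug_ml"], sort=True)
        .agg(pc1_mean=("pc1", "mean"), pc2_mean=("pc2", "mean"), n=("pc1", "size"))
        .reset_index()
    )
    out_rows = []
    for (line, day), grp in grouped.groupby(["cell_line", "day"], sort=True):
        ctrl = grp[grp["concentration_ug_ml"] == 0]
        if ctrl.empty:
            raise ValueError(f"missing control group for ({line}, day {day})")
        c1 = float(ctrl["pc1_mean"].iloc[0])
        c2 = float(ctrl["pc2_mean"].iloc[0])
        g = grp.copy()
        g["distance"] = np.hypot(g["pc1_mean"] - c1, g["pc2_mean"] - c2)
        g.loc[g["concentration_ug_ml"] == 0, "distance"] = 0.0
        out_rows.append(g)
    return pd.concat(out_rows, ignore_index=True)


def quartile_thresholds(distances) -> tuple[float, float]:
    """(q25, q75) of pooled treatment distances, linear-interpolation
    quantile convention."""
    d = np.asarray(distances, dtype=float)
    if d.size < 4:
        raise ValueError("need at least 4 treatment distances")
    q25, q75 = np.quantile(d, [0.25, 0.75], method="linear")
    return float(q25), float(q75)


def classify_distances(distances) -> tuple[list[str], float, float]:
    """Class per distance: low if d <= q25, high if d >= q75, otherwise
    intermediate.  When q25 == q75 the low rule wins at the boundary."""
    d = np.asarray(distances, dtype=float)
    q25, q75 = quartile_thresholds(d)
    classes = [
        "low" if x <= q25 else ("high" if x >= q75 else "intermediate")
        for x in d
    ]
    return classes, q25, q75


def classify_responses(table: pd.DataFrame
                       ) -> tuple[pd.DataFrame, float, float]:
    """Attach response classes to a group-distance table.  Thresholds come
    from the pooled treatment (concentration > 0) distances; control rows
    are left unclassified (class = 'control')."""
    out = table.copy()
    treated = out["concentration_ug_ml"] > 0
    classes, q25, q75 = classify_distances(out.loc[treated, "distance"])
    out["response_class"] = "control"
    out.loc[treated, "response_class"] = classes
    return out, q25, q75
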