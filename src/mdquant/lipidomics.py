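"""Lipid-amount-table post-processing.

Pi (inorganic phosphate) normalization, log2 fold changes against
per-strain controls, lipid-class pooling, PCA with per-lipid component
contributions, and protein-lipid Pearson correlation with a two-tailed
significance gate and the mean significant coefficient mu_r.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LipidTable",
    "PCAResult",
    "CorrelationResult",
    "pi_normalize",
    "log2_fold_change",
    "class_pool",
    "pca",
    "protein_lipid_correlation",
]


@dataclass
class LipidTable:
    """Samples x lipids amounts with per-sample Pi and a lipid->class map.

    ``amounts`` rows are keyed by a (strain, condition, replicate)
    MultiIndex; ``pi`` shares that index.
    """

    amounts: pd.DataFrame
    pi: pd.Series
    class_map: dict[str, str]

    def __post_init__(self) -> None:
        if not self.amounts.index.equals(self.pi.index):
            missing = self.amounts.index.difference(self.pi.index)
            if len(missing):
                raise ValueError(f"missing Pi value for sample(s): {list(missing)}")
            self.pi = self.pi.reindex(self.amounts.index)
        if (self.pi <= 0).any():
            bad = self.pi.index[self.pi <= 0].tolist()
            raise ValueError(f"Pi must be positive; offending sample(s): {bad}")
        unmapped = [l for l in self.amounts.columns if l not in self.class_map]
        if unmapped:
            raise ValueError(f"lipid(s) without a class: {unmapped}")
        if (self.amounts.to_numpy() < 0).any():
            raise ValueError("amounts must be non-negative")

    @property
    def lipids(self) -> list[str]:
        return list(self.amounts.columns)


def pi_normalize(table: LipidTable) -> LipidTable:
    """Divide each sample's amounts by its Pi value.

    The returned table has Pi reset to 1, so a second pass is the
    identity.
    """
    normalized = table.amounts.div(table.pi, axis=0)
    return LipidTable(
        amounts=normalized,
        pi=pd.Series(1.0, index=table.amounts.index, name="pi"),
        class_map=dict(table.class_map),
    )


def class_pool(table: LipidTable) -> LipidTable:
    """Sum amounts within each lipid class, per sample."""
    classes = pd.Series({l: table.class_map[l] for l in table.amounts.columns})
    pooled = table.amounts.T.groupby(classes).sum().T
    return LipidTable(
        amounts=pooled,
        pi=table.pi.copy(),
        class_map={c: c for c in pooled.columns},
    )


def log2_fold_change(
    table: LipidTable,
    control_condition: str = "control",
    reference_strain: str | None = None,
    pseudo_amount: float | None = None,
) -> pd.DataFrame:
    """Log2 fold-change matrix (lipids x treatments).

    Each (strain, condition) is compared against the mean of the same
    strain's control replicates; in addition, every non-reference
    strain's control is compared against the reference strain's control.
    Zero amounts are replaced by ``pseudo_amount`` (default: half the
    smallest nonzero amount in the table) before forming ratios.
    """
    amounts = table.amounts
    strains = amounts.index.get_level_values("strain").unique()
    conditions = amounts.index.get_level_values("condition").unique()
    if control_condition not in conditions:
        raise ValueError(f"no control replicates found for {control_condition!r}")
    if pseudo_amount is None:
        nonzero = amounts.to_numpy()[amounts.to_numpy() > 0]
        pseudo_amount = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
    amounts = amounts.where(amounts > 0, pseudo_amount)
    if reference_strain is None:
        reference_strain = strains[0]

    def mean_of(strain: str, condition: str) -> pd.Series | None:
        sel = (amounts.index.get_level_values("strain") == strain) & (
            amounts.index.get_level_values("condition") == condition
        )
        if not sel.any():
            return None
        return amounts.loc[sel].mean(axis=0)

    columns: dict[str, pd.Series] = {}
    for strain in strains:
        ctrl = mean_of(strain, control_condition)
        if ctrl is None:
            raise ValueError(f"strain {strain!r} has no control replicates")
        for condition in conditions:
            if condition == control_condition:
                continue
            trt = mean_of(strain, condition)
            if trt is None:
                continue
            columns[f"{strain}:{condition}"] = np.log2(trt / ctrl)
        if strain != reference_strain:
            ref_ctrl = mean_of(reference_strain, control_condition)
            columns[f"{strain}:{control_condition}"] = np.log2(ctrl / ref_ctrl)
    return pd.DataFrame(columns)


@dataclass
class PCAResult:
    """PCA of a sample x lipid matrix.

    ``loadings`` columns are unit-norm; ``contributions`` holds
    100 * loading**2, which sums to 100 per component.
    """

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # lipids x components
    explained_variance_fraction: np.ndarray
    contributions: pd.DataFrame  # lipids x components, percent

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(table: LipidTable | pd.DataFrame, scaling: str = "auto") -> PCAResult:
    """Principal-component analysis of the amount matrix.

    ``scaling="auto"`` (default) centers each lipid column and scales it
    to unit variance; ``scaling="center"`` only centers.  Components are
    computed by SVD; the sign convention makes the largest-magnitude
    loading of each component positive.
    """
    amounts = table.amounts if isinstance(table, LipidTable) else table
    if amounts.shape[0] < 3 or amounts.shape[1] < 2:
        raise ValueError("pca requires >= 3 samples and >= 2 lipids")
    if amounts.isna().any().any():
        raise ValueError("pca input must not contain missing values")
    if scaling not in ("auto", "center"):
        raise ValueError("scaling must be 'auto' or 'center'")
    x = amounts.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scaling == "auto":
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [amounts.columns[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant lipid column(s) under auto scaling: {bad}")
        x = x / sd

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    var = s**2 / (n - 1)
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)

    # sign convention: the largest-|loading| entry of each component positive
    flip = np.where(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)] < 0, -1.0, 1.0)
    vt = vt * flip[:, None]
    scores = (u * s) * flip[None, :]

    comp_names = [f"PC{i + 1}" for i in range(s.size)]
    loadings = pd.DataFrame(vt.T, index=amounts.columns, columns=comp_names)
    return PCAResult(
        scores=pd.DataFrame(scores, index=amounts.index, columns=comp_names),
        loadings=loadings,
        explained_variance_fraction=explained,
        contributions=100.0 * loadings**2,
    )


@dataclass
class CorrelationResult:
    """Per-lipid protein correlation with a p <= alpha significance gate."""

    table: pd.DataFrame  # index lipid; columns r, p, significant, flag
    alpha: float

    @property
    def mu_r(self) -> float:
        """Mean Pearson r over significant lipids; NaN if none."""
        sig = self.table.loc[self.table["significant"], "r"]
        return float(sig.mean()) if len(sig) else np.nan


def protein_lipid_correlation(
    protein: pd.Series,
    table: LipidTable,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson correlation of protein amount vs each lipid across conditions.

    ``protein`` is indexed by condition; lipid amounts are averaged to
    condition level before correlating, matching keys exactly.  Two-tailed
    p-values come from the t distribution with n-2 df.  Lipids with zero
    variance are excluded with a flag.
    """
    cond_means = table.amounts.groupby(level="condition").mean()
    unmatched = sorted(set(protein.index) ^ set(cond_means.index))
    if unmatched:
        raise ValueError(f"condition keys do not match: {unmatched}")
    cond_means = cond_means.reindex(protein.index)
    n = len(protein)
    if n < 3:
        raise ValueError("need >= 3 paired conditions")
    x = protein.to_numpy(dtype=float)
    rows = []
    for lipid in cond_means.columns:
        y = cond_means[lipid].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(x) == 0:
            rows.append((lipid, np.nan, np.nan, False, "constant"))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((lipid, float(r), float(p), bool(p <= alpha), ""))
    df = pd.DataFrame(rows, columns=["lipid", "r", "p", "significant", "flag"])
    return CorrelationResult(table=df.set_index("lipid"), alpha=alpha)
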