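"""Synthetic sample x lipid amount tables with class-structured effects.

Amounts are log-normal around a per-lipid base level, scaled by a
multiplicative (condition, class) shift and then by a per-sample Pi
factor, so that Pi normalization is required to recover the shifts.  A
per-condition protein-amount table is constructed to correlate with a
designated lipid class at a target Pearson rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from ..lipidomics import LipidTable

__all__ = ["LipidSimParams", "generate_lipid_dataset"]


@dataclass(frozen=True)
class LipidSimParams:
    """Parameters of one synthetic lipid dataset.

    ``conditions`` must include ``control_condition``.  ``lipid_classes``
    maps class name -> number of lipid species in that class.
    ``condition_class_shifts`` maps (condition, class) -> multiplicative
    effect relative to control (default 1.0).
    """

    conditions: tuple[str, ...] = ("control", "heat", "ethanol")
    control_condition: str = "control"
    strain: str = "wt"
    n_replicates: int = 4
    lipid_classes: dict = dc_field(
        default_factory=lambda: {"LCB": 3, "Cer": 4, "IPC": 5, "MIPC": 4}
    )
    base_amount_log_mean: float = 3.0
    base_amount_log_sd: float = 1.0
    condition_class_shifts: dict = dc_field(default_factory=dict)
    pi_scale_range: tuple[float, float] = (0.5, 2.0)
    protein_class: str | None = None  # defaults to the first class
    protein_lipid_rho: float = 0.9
    noise_cv: float = 0.0
    seed: int = 0

    def shifts(self) -> dict:
        """Shift map with (condition, class) tuple keys; string keys of the
        form ``"condition|class"`` (YAML-friendly) are accepted too."""
        out = {}
        for key, v in self.condition_class_shifts.items():
            if isinstance(key, str):
                cond, _, cls = key.partition("|")
                out[(cond, cls)] = v
            else:
                out[tuple(key)] = v
        return out

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.control_condition not in self.conditions:
            raise ValueError("conditions must include the control condition")
        if not self.lipid_classes:
            raise ValueError("at least one lipid class is required")
        classes = set(self.lipid_classes)
        for (cond, cls), shift in self.shifts().items():
            if cls not in classes:
                raise ValueError(f"unknown lipid class in shifts: {cls!r}")
            if cond not in self.conditions:
                raise ValueError(f"unknown condition in shifts: {cond!r}")
            if shift <= 0:
                raise ValueError("condition_class_shifts must be > 0")
        if not 0.0 <= abs(self.protein_lipid_rho) <= 1.0:
            raise ValueError("|protein_lipid_rho| must be <= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        lo, hi = self.pi_scale_range
        if not (0 < lo <= hi):
            raise ValueError("pi_scale_range must satisfy 0 < min <= max")


def generate_lipid_dataset(
    params: LipidSimParams,
) -> tuple[LipidTable, pd.DataFrame, dict]:
    """Generate (lipid table, per-condition protein amounts, truth record)."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    lipid_names: list[str] = []
    class_map: dict[str, str] = {}
    for cls, n in params.lipid_classes.items():
        for i in range(int(n)):
            name = f"{cls}_{i + 1}"
            lipid_names.append(name)
            class_map[name] = cls

    base = np.exp(
        rng.normal(params.base_amount_log_mean, params.base_amount_log_sd, len(lipid_names))
    )

    # multiplicative log-normal measurement noise with the requested CV,
    # mean-corrected so E[noise] == 1
    if params.noise_cv > 0:
        sig = np.sqrt(np.log1p(params.noise_cv**2))
    else:
        sig = 0.0

    index = pd.MultiIndex.from_tuples(
        [
            (params.strain, cond, rep + 1)
            for cond in params.conditions
            for rep in range(params.n_replicates)
        ],
        names=["strain", "condition", "replicate"],
    )
    shift_map = params.shifts()
    amounts = np.empty((len(index), len(lipid_names)))
    pi_factors = rng.uniform(*params.pi_scale_range, size=len(index))
    for si, (_, cond, _) in enumerate(index):
        shifts = np.array(
            [shift_map.get((cond, class_map[l]), 1.0) for l in lipid_names]
        )
        if sig > 0:
            noise = np.exp(rng.normal(-0.5 * sig**2, sig, len(lipid_names)))
        else:
            noise = 1.0
        amounts[si] = base * shifts * noise * pi_factors[si]

    table = LipidTable(
        amounts=pd.DataFrame(amounts, index=index, columns=lipid_names),
        pi=pd.Series(pi_factors, index=index, name="pi"),
        class_map=class_map,
    )

    # protein amounts correlated with the designated class' condition means
    target_class = params.protein_class or next(iter(params.lipid_classes))
    norm = table.amounts.div(table.pi, axis=0)
    class_cols = [l for l, c in class_map.items() if c == target_class]
    class_mean = norm[class_cols].sum(axis=1).groupby(level="condition").mean()
    class_mean = class_mean.reindex(list(params.conditions))
    x = class_mean.to_numpy()
    xs = x.std()
    z = (x - x.mean()) / xs if xs > 0 else np.zeros_like(x)
    e = rng.normal(size=x.size)
    if e.std() > 0:
        e = (e - e.mean()) / e.std()
    rho = params.protein_lipid_rho
    latent = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * e
    protein = np.clip(1.0 + 0.25 * latent, 0.05, None)
    protein_df = pd.DataFrame(
        {"condition": list(params.conditions), "protein_amount": protein}
    )

    truth = {
        "condition_class_shifts": {
            f"{cond}|{cls}": shift for (cond, cls), shift in shift_map.items()
        },
        "protein_class": target_class,
        "protein_lipid_rho": params.protein_lipid_rho,
        "pi_factors": pi_factors.tolist(),
        "seed": params.seed,
    }
    return table, protein_df, truth
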