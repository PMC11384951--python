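"""Synthetic two-arm ICU cohort generator.

Simulates longitudinal patient-day "state vectors" for a therapeutic drug
monitoring (TDM) vs. control trial: each patient carries six latent organ
dysfunction levels (respiratory, cardiovascular, hepatic, coagulation,
renal, neurological) that decay exponentially at an arm-specific recovery
rate.  Observed features are noisy linear mixtures of the latent state
(informative features) or pure noise, plus baseline pathogen flags.  Organ
subscores are threshold bins of the latent levels, summed to a 0-24
severity total, mirroring how sequential organ failure assessment (SOFA)
scoring aggregates organ systems.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ORGAN_SYSTEMS = (
    "respiratory",
    "cardiovascular",
    "hepatic",
    "coagulation",
    "renal",
    "neurological",
)

N_ORGANS = len(ORGAN_SYSTEMS)

#: Equal-width latent bin per subscore point; latent >= 4*width maps to 4.
SOFA_BIN_WIDTH = 1.0

ARM_TDM = "TDM"
ARM_CONTROL = "control"

EXIT_IN_STUDY = "in_study"
EXIT_ALIVE = "left_alive"
EXIT_DEAD = "left_dead"

SOFA_COLUMNS = tuple(f"sofa_{o}" for o in ORGAN_SYSTEMS)
KEY_COLUMNS = ("patient_id", "arm", "day")
META_COLUMNS = KEY_COLUMNS + SOFA_COLUMNS + ("sofa_total", "exit_status")

# Initial per-organ dysfunction severity: Gamma(shape, scale).  Chosen so the
# day-1 severity total is ~9 with a spread of ~2, typical of a septic ICU
# admission cohort.
_INIT_SHAPE = 3.0
_INIT_SCALE = 0.55


@dataclass
class CohortConfig:
    """Parameters of the synthetic trial cohort.

    ``recovery_rate_tdm >= recovery_rate_control`` encodes a beneficial
    monitoring effect; equality encodes the null.  Rates are per day and act
    multiplicatively on the latent organ dysfunction from
    ``effect_onset_day`` onward (before onset both arms recover at the
    control rate).
    """

    n_tdm: int = 123
    n_control: int = 125
    n_continuous: int = 12
    n_discrete: int = 6
    n_pathogen: int = 4
    n_informative: int = 15
    max_days: int = 10
    recovery_rate_control: float = 0.08
    recovery_rate_tdm: float = 0.12
    effect_onset_day: int = 2
    obs_noise_sd: float = 0.3
    death_hazard_scale: float = 0.004
    discharge_sofa_threshold: int = 1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_tdm": self.n_tdm,
            "n_control": self.n_control,
            "n_continuous": self.n_continuous,
            "n_discrete": self.n_discrete,
            "n_pathogen": self.n_pathogen,
            "n_informative": self.n_informative,
            "max_days": self.max_days,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_tdm + self.n_control == 0:
            raise ValueError("cohort must contain at least one patient")
        if self.n_continuous + self.n_discrete + self.n_pathogen == 0:
            raise ValueError("cohort must contain at least one feature")
        if self.n_informative > self.n_continuous + self.n_discrete:
            raise ValueError(
                "n_informative cannot exceed n_continuous + n_discrete"
            )
        if self.max_days < 1:
            raise ValueError("max_days must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.recovery_rate_control < 0 or self.recovery_rate_tdm < 0:
            raise ValueError("recovery rates must be nonnegative")

    @property
    def feature_names(self) -> list[str]:
        return (
            [f"cont_{i:02d}" for i in range(self.n_continuous)]
            + [f"disc_{i:02d}" for i in range(self.n_discrete)]
            + [f"path_{i:02d}" for i in range(self.n_pathogen)]
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


def compute_sofa(latent_levels) -> tuple[np.ndarray, int]:
    """Map six latent organ dysfunction levels to subscores and a total.

    Each subscore is the equal-width bin of its latent level, clamped to
    0..4; the total is the plain sum (0..24).  Different organ profiles can
    share a total — the degeneracy that motivates a multidimensional view of
    the score.
    """
    latent = np.asarray(latent_levels, dtype=float)
    if latent.shape[-1] != N_ORGANS:
        raise ValueError(
            f"expected {N_ORGANS} organ levels, got {latent.shape[-1]}"
        )
    if np.any(latent < 0):
        raise ValueError("latent dysfunction levels must be nonnegative")
    subscores = np.clip(
        np.floor(latent / SOFA_BIN_WIDTH).astype(int), 0, 4
    )
    return subscores, int(subscores.sum(axis=-1)) if subscores.ndim == 1 else subscores.sum(axis=-1)


def _structure(config: CohortConfig, rng: np.random.Generator):
    """Fixed (seed-determined) mixing structure shared by all patients."""
    n_cont, n_disc = config.n_continuous, config.n_discrete
    n_inf_cont = min(config.n_informative, n_cont)
    n_inf_disc = config.n_informative - n_inf_cont

    def _mixing(n_rows: int, offset: int = 0) -> np.ndarray:
        # Each informative feature loads mainly on one primary organ system
        # (as clinical markers do) with a weaker spread over the others;
        # unit L1 norm so observed = w . latent + noise stays on the latent
        # scale.
        w = rng.uniform(0.02, 0.12, size=(n_rows, N_ORGANS))
        for j in range(n_rows):
            w[j, (j + offset) % N_ORGANS] += 0.6
        return w / w.sum(axis=1, keepdims=True)

    w_cont = _mixing(n_inf_cont)
    w_disc = _mixing(n_inf_disc, offset=n_inf_cont)
    prevalence = rng.uniform(0.05, 0.4, size=config.n_pathogen)
    # Ordinal cut points for discrete codes 0..4 on the mixed latent scale.
    disc_cuts = np.array([0.5, 1.0, 1.5, 2.5])
    return w_cont, w_disc, prevalence, disc_cuts


def generate_cohort(
    config: CohortConfig, return_latent: bool = False
) -> pd.DataFrame:
    """Simulate one cohort; returns a wide frame, one row per patient-day.

    Both arms draw identical initial-severity distributions (exchangeable at
    day 1); the treatment effect enters only through the recovery rate from
    ``effect_onset_day`` onward.  A patient exits dead with a per-day hazard
    increasing in total dysfunction, or alive once the severity total drops
    to ``discharge_sofa_threshold``; otherwise the trajectory is censored at
    ``max_days``.
    """
    rng = np.random.default_rng(config.seed)
    w_cont, w_disc, prevalence, disc_cuts = _structure(config, rng)
    n_inf_cont = w_cont.shape[0]
    n_inf_disc = w_disc.shape[0]
    n_noise_cont = config.n_continuous - n_inf_cont
    n_noise_disc = config.n_discrete - n_inf_disc

    rows: list[dict] = []
    latent_rows: list[dict] = []
    arms = [ARM_TDM] * config.n_tdm + [ARM_CONTROL] * config.n_control
    for idx, arm in enumerate(arms):
        pid = f"P{idx:04d}"
        latent = rng.gamma(_INIT_SHAPE, _INIT_SCALE, size=N_ORGANS)
        pathogens = (rng.uniform(size=config.n_pathogen) < prevalence).astype(int)
        arm_rate = (
            config.recovery_rate_tdm if arm == ARM_TDM
            else config.recovery_rate_control
        )
        for day in range(1, config.max_days + 1):
            if day > 1:
                rate = (
                    arm_rate if day >= config.effect_onset_day
                    else config.recovery_rate_control
                )
                latent = latent * np.exp(-rate)
            subscores, total = compute_sofa(latent)
            feats: dict[str, float | int] = {}
            signal_c = w_cont @ latent
            noise = rng.normal(0.0, config.obs_noise_sd, size=config.n_continuous)
            for j in range(n_inf_cont):
                feats[f"cont_{j:02d}"] = signal_c[j] + noise[j]
            for j in range(n_noise_cont):
                feats[f"cont_{n_inf_cont + j:02d}"] = noise[n_inf_cont + j]
            if n_inf_disc:
                signal_d = w_disc @ latent + rng.normal(
                    0.0, config.obs_noise_sd, size=n_inf_disc
                )
                codes = np.digitize(signal_d, disc_cuts)
                for j in range(n_inf_disc):
                    feats[f"disc_{j:02d}"] = int(codes[j])
            for j in range(n_noise_disc):
                feats[f"disc_{n_inf_disc + j:02d}"] = int(rng.integers(0, 5))
            for j in range(config.n_pathogen):
                feats[f"path_{j:02d}"] = int(pathogens[j])

            exit_status = EXIT_IN_STUDY
            if total <= config.discharge_sofa_threshold:
                exit_status = EXIT_ALIVE
            else:
                p_death = 1.0 - np.exp(
                    -config.death_hazard_scale * float(latent.sum())
                )
                if rng.uniform() < p_death:
                    exit_status = EXIT_DEAD
            row = {
                "patient_id": pid,
                "arm": arm,
                "day": day,
                **feats,
                **{c: int(s) for c, s in zip(SOFA_COLUMNS, subscores)},
                "sofa_total": int(total),
                "exit_status": exit_status,
            }
            rows.append(row)
            if return_latent:
                latent_rows.append(
                    {
                        "patient_id": pid,
                        "arm": arm,
                        "day": day,
                        **{o: float(v) for o, v in zip(ORGAN_SYSTEMS, latent)},
                    }
                )
            if exit_status != EXIT_IN_STUDY:
                break

    df = pd.DataFrame(rows)
    ordered = list(KEY_COLUMNS) + config.feature_names + list(SOFA_COLUMNS) + [
        "sofa_total",
        "exit_status",
    ]
    df = df[ordered]
    if return_latent:
        return df, pd.DataFrame(latent_rows)
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Feature columns of a wide cohort frame (everything non-meta)."""
    return [c for c in df.columns if c not in META_COLUMNS]


def inject_missingness(
    df: pd.DataFrame, missing_rate: float, seed: int
) -> pd.DataFrame:
    """Blank each feature cell independently with probability ``missing_rate``.

    Identifier, severity-score and exit columns are never blanked.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    out = df.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    cols = feature_columns(df)
    mask = rng.uniform(size=(len(df), len(cols))) < missing_rate
    values = out[cols].astype(float).to_numpy()
    values[mask] = np.nan
    out[cols] = values
    return out


def to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Wide (one row per patient-day) to long (one row per value)."""
    value_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    long = df.melt(
        id_vars=list(KEY_COLUMNS), value_vars=value_cols,
        var_name="feature", value_name="value",
    )
    return long.sort_values(["patient_id", "day", "feature"]).reset_index(drop=True)


def to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_long`; dtypes are restored heuristically."""
    wide = long.pivot_table(
        index=list(KEY_COLUMNS), columns="feature", values="value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    for col in wide.columns:
        if col in KEY_COLUMNS or col == "exit_status":
            continue
        wide[col] = pd.to_numeric(wide[col], errors="coerce")
    return wide


def write_cohort(
    df: pd.DataFrame,
    path: str | Path,
    format: str = "wide",
    config: CohortConfig | None = None,
    sep: str = ",",
) -> Path:
    """Write a cohort as CSV/TSV plus a JSON sidecar with dtypes and config.

    The sidecar makes the write/read round trip exact (values and dtypes).
    """
    if len(df) == 0:
        raise ValueError("refusing to write an empty cohort")
    if format not in ("wide", "long"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    out = df if format == "wide" else to_long(df)
    out.to_csv(path, index=False, sep=sep)
    sidecar = {
        "format": format,
        "sep": sep,
        "dtypes": {c: str(t) for c, t in df.dtypes.items()},
        "columns": list(df.columns),
        "config": config.to_dict() if config is not None else None,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1)
    )
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort written by :func:`write_cohort`."""
    path = Path(path)
    meta = json.loads(
        path.with_suffix(path.suffix + ".meta.json").read_text()
    )
    raw = pd.read_csv(path, sep=meta["sep"])
    if meta["format"] == "long":
        raw = to_wide(raw)
    raw = raw[meta["columns"]]
    for col, dtype in meta["dtypes"].items():
        raw[col] = raw[col].astype(dtype)
    return raw.reset_index(drop=True)
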