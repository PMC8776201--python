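"""Synthetic "virtual mouse" blood-glucose datasets.

The generator runs the assumed data-generating process forwards: a
deterministic model trajectory observed at a handful of time points with
i.i.d. additive Gaussian measurement noise.  Four named severity presets
emulate the qualitative regimes seen in small experimental mouse groups:

``hyperglycaemic``
    a sharp episode peaking near 400 mg/dL before insulin brings glucose
    back down;
``hypoglycaemic``
    an early dip below 70 mg/dL driven by excess circulating insulin,
    followed by recovery into the expected 70–200 mg/dL range;
``moderate``
    a diabetic but bounded excursion, maximum between 200 and 260 mg/dL;
``controlled``
    glucose held within the expected 70–200 mg/dL range throughout.

The default observation grid merges the clinically significant
post-prandial monitoring times (30, 60, 90, 180, 210 min) with t = 0 and
one extra interior point, giving seven observations over 0–210 min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .models import AnyParameters, Model1Parameters, StateVector
from .simulate import simulate

__all__ = [
    "GlucoseDataset",
    "SeverityPreset",
    "PROFILES",
    "DEFAULT_TIMES",
    "DEFAULT_NOISE_SD",
    "GLUCOSE_FLOOR",
    "generate_dataset",
    "severity_preset",
    "generate_preset_dataset",
]

logger = logging.getLogger(__name__)

#: default observation grid (minutes)
DEFAULT_TIMES: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 210.0)
#: default measurement-noise standard deviation (mg/dL), ~5–10% of normal glucose
DEFAULT_NOISE_SD: float = 10.0
#: observations are truncated below at this value (mg/dL)
GLUCOSE_FLOOR: float = 1.0

PROFILES: tuple[str, ...] = ("hyperglycaemic", "hypoglycaemic", "moderate", "controlled")


@dataclass(frozen=True)
class GlucoseDataset:
    """Observed time/glucose pairs plus generation metadata."""

    times: np.ndarray  # minutes
    glucose: np.ndarray  # mg/dL
    profile: Optional[str] = None
    truth: Optional[dict] = None  # generating parameters, init and noise SD
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.glucose, dtype=float)
        if t.shape != g.shape or t.ndim != 1:
            raise ValueError("times and glucose must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValueError("dataset must contain at least one observation")
        if not np.all(np.isfinite(g)) or np.any(g <= 0):
            raise ValueError("glucose values must be finite and > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "glucose", g)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "glucose_mg_dl": self.glucose})

    def to_csv(self, path: Union[str, Path], sidecar: bool = True) -> None:
        """Write observations as TSV; metadata goes to ``<path>.meta.yaml``."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {"profile": self.profile, "seed": self.seed, "truth": self.truth}
            Path(f"{path}.meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "GlucoseDataset":
        path = Path(path)
        frame = pd.read_csv(path, sep=None, engine="python")
        meta_path = Path(f"{path}.meta.yaml")
        meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            times=frame["time_min"].to_numpy(float),
            glucose=frame["glucose_mg_dl"].to_numpy(float),
            profile=(meta or {}).get("profile"),
            truth=(meta or {}).get("truth"),
            seed=(meta or {}).get("seed"),
        )


class SeverityPreset(NamedTuple):
    model_id: int
    params: AnyParameters
    init: StateVector
    times: tuple[float, ...]


# Generating configurations, tuned within plausible parameter ranges so that
# each noiseless trajectory satisfies its profile's glucose band, then frozen.
_PRESETS: dict[str, SeverityPreset] = {
    # peak ~390 mg/dL at ~22 min, declining to ~123 mg/dL as insulin builds up
    "hyperglycaemic": SeverityPreset(
        model_id=1,
        params=Model1Parameters(psi=0.02, delta=0.025, a=45.0, b=0.08, c=0.1),
        init=StateVector(I=0.1, GL=80.0, GH=30.0),
        times=DEFAULT_TIMES,
    ),
    # excess initial insulin drives a dip to ~31 mg/dL, recovery to ~143 mg/dL
    "hypoglycaemic": SeverityPreset(
        model_id=1,
        params=Model1Parameters(psi=0.005, delta=0.045, a=16.0, b=0.11, c=0.06),
        init=StateVector(I=9.0, GL=120.0, GH=30.0),
        times=DEFAULT_TIMES,
    ),
    # bounded excursion peaking at ~222 mg/dL
    "moderate": SeverityPreset(
        model_id=1,
        params=Model1Parameters(psi=0.02, delta=0.05, a=28.0, b=0.09, c=0.1),
        init=StateVector(I=0.2, GL=120.0, GH=30.0),
        times=DEFAULT_TIMES,
    ),
    # glucose drifts from 100 to ~127 mg/dL, always inside 70–200
    "controlled": SeverityPreset(
        model_id=1,
        params=Model1Parameters(psi=0.02, delta=0.08, a=16.0, b=0.1, c=0.1),
        init=StateVector(I=0.5, GL=100.0, GH=30.0),
        times=DEFAULT_TIMES,
    ),
}


def severity_preset(profile: str) -> SeverityPreset:
    """Frozen generating configuration for a named severity profile."""
    try:
        return _PRESETS[profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; expected one of {PROFILES}"
        ) from None


def generate_dataset(model_id: int,
                     params: AnyParameters,
                     init: StateVector,
                     times=DEFAULT_TIMES,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     seed: Optional[int] = None,
                     profile: Optional[str] = None,
                     rng: Optional[np.random.Generator] = None) -> GlucoseDataset:
    """Simulate a model and observe its glucose channel with Gaussian noise.

    ``glucose[j] = GL(times[j]) + eps_j`` with ``eps_j ~ N(0, noise_sd^2)``,
    truncated below at ``GLUCOSE_FLOOR`` (negative glucose is unphysical;
    truncation events are logged since they slightly bias the noise model).
    The same ``seed`` always reproduces the same dataset.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    trajectory = simulate(model_id, params, init, times)
    clean = np.clip(trajectory.glucose, 0.0, None)
    if rng is None:
        rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean.copy()
    n_truncated = int(np.sum(noisy < GLUCOSE_FLOOR))
    if n_truncated:
        logger.info("truncated %d observation(s) at the %.1f mg/dL floor",
                    n_truncated, GLUCOSE_FLOOR)
    noisy = np.maximum(noisy, GLUCOSE_FLOOR)
    truth = {
        "model_id": model_id,
        "params": params.to_dict(),
        "init": {n: getattr(init, n) for n in ("I", "GL", "GH", "beta")},
        "noise_sd": float(noise_sd),
    }
    return GlucoseDataset(times=np.asarray(times, float), glucose=noisy,
                          profile=profile, truth=truth, seed=seed)


def generate_preset_dataset(profile: str,
                            noise_sd: float = DEFAULT_NOISE_SD,
                            seed: Optional[int] = None,
                            rng: Optional[np.random.Generator] = None) -> GlucoseDataset:
    """Generate a dataset from a named severity preset."""
    preset = severity_preset(profile)
    return generate_dataset(preset.model_id, preset.params, preset.init,
                            preset.times, noise_sd=noise_sd, seed=seed,
                            profile=profile, rng=rng)
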