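"""Bundled reference datasets and calibrated coefficients.

Small published reference measurements from single-point-diamond-tool cutting
trials on bovine cortical bone, transcribed for offline use: replicate
ploughing coefficients at the three osteon cutting angles (five replicates
each at 0°, 45°, 90°, UCT 0.7 mm) and per-replicate tangential-force
measurements over the factorial of UCT and angle, plus the published
calibrated coefficient set for the normal-force power law and the anisotropy
sinusoid.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import AnisotropyModel, NormalForceModel
from .io import coefficients_from_dict

__all__ = [
    "load_replicate_ploughing_coefficients",
    "load_tangential_force_trials",
    "reference_coefficients",
    "reference_normal_force_model",
    "reference_anisotropy_model",
]


def _data_path(name: str):
    return resources.files("boneplough.data").joinpath(name)


def load_replicate_ploughing_coefficients() -> pd.DataFrame:
    """Replicate ploughing coefficients f_p by cutting angle.

    Columns: theta_deg, fp, replicate — five replicates at each of 0°, 45°,
    90°, measured at 0.7 mm uncut chip thickness.
    """
    with resources.as_file(_data_path("replicate_ploughing_coefficients.csv")) as p:
        return pd.read_csv(p)


def load_tangential_force_trials() -> pd.DataFrame:
    """Per-replicate measured tangential forces (N) over the factorial design.

    Columns: h_mm, theta_deg, fp_n, replicate — five replicates at each of
    UCT {0.5, 0.6, 0.8} mm × angle {0°, 45°, 90°}.
    """
    with resources.as_file(_data_path("tangential_force_trials.csv")) as p:
        return pd.read_csv(p)


def reference_coefficients() -> tuple[NormalForceModel, AnisotropyModel]:
    """The published calibrated coefficient set as model objects."""
    import yaml

    with resources.as_file(_data_path("reference_coefficients.yaml")) as p:
        d = yaml.safe_load(p.read_text())
    return coefficients_from_dict(d)


def reference_normal_force_model() -> NormalForceModel:
    """Calibrated power law Fz = 707.53·V^0.39."""
    return reference_coefficients()[0]


def reference_anisotropy_model() -> AnisotropyModel:
    """Calibrated sinusoid f_p(θ) = 0.294 + 0.934·sin(0.45·θ) (radians)."""
    return reference_coefficients()[1]
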