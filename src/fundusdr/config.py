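"""Run configuration: every tunable threshold of the pipeline in one
flat, documented namespace, loadable from a YAML file.

All spatial parameters are expressed relative to a 512-px frame or to the
estimated disc/ROI radius, so behavior transfers across resolutions.
Unknown keys in a user file are rejected (typos should fail loudly).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._exceptions import ConfigurationError


@dataclass
class RunConfig:
    # --- global ---
    seed: int = 0
    out_dir: str = "fundusdr_out"
    verbosity: int = 1
    write_overlays: bool = True
    report_format: str = "csv"  # csv | json

    # --- preprocess ---
    roi_min_frac: float = 0.20          # min field fraction of the frame
    roi_adaptive_offset: float = 10.0   # gray levels below local mean
    roi_dark_floor: float = 18.0        # absolute luminance floor for field px
    roi_full_frame_frac: float = 0.98   # above this, assume no black border
    denoise_radius: int = 1             # median filter radius, px
    color_space: str = "hsv"            # lightness/saturation decomposition
    profile_percentiles: tuple[float, float] = (1.0, 99.0)

    # --- anatomy ---
    vessel_n_orientations: int = 12
    vessel_line_lengths: tuple[int, ...] = (7, 11, 17)  # scales at 512 px
    vessel_threshold: float = 4.0       # line-response threshold, gray levels
    vessel_min_component_px: int = 30   # at 512 px, scaled by (W/512)^2
    vessel_use_classifier: bool = True
    vessel_decision_shift: float = 0.0  # classifier operating point (recall side)
    disc_radius_frac: float = 0.16      # search radius as fraction of ROI radius
    disc_brightness_weight: float = 0.45
    disc_circularity_weight: float = 0.25
    disc_convergence_weight: float = 0.30
    disc_confidence_gate: float = 0.35
    macula_offset_frac: float = 0.5     # posterior-pole shift, fraction of ROI radius

    # --- lesions ---
    ma_max_area_px: int = 30            # MA/hemorrhage boundary at 512 px
    red_small_tophat_div: float = 15.0  # SE radius = disc_radius / this
    red_tophat_threshold: float = 8.0   # gray levels
    red_color_value_max: float = 0.40   # large red lesions: max HSV value
    red_min_area_px: int = 6
    vessel_overlap_max: float = 0.20    # candidates overlapping vessels >= this are dropped
    disc_exclusion_scale: float = 1.3   # disc radius multiplier for exclusion zone
    bright_tophat_div: float = 8.0      # SE radius = disc_radius / this
    bright_threshold: float = 18.0      # gray levels above background
    bright_min_area_px: int = 5
    exudate_gradient_cut: float = 14.0  # boundary gradient separating exudate/cottonwool
    cottonwool_min_area_px: int = 120
    prp_annulus_frac: float = 0.55      # scars searched outside this ROI-radius fraction
    prp_min_count: int = 15             # spots needed to call a PRP pattern
    prp_area_cv_max: float = 0.6        # size regularity bound
    prp_min_area_px: int = 20
    prp_max_area_px: int = 800

    # --- grading ---
    hq_per_quadrant: int = 20           # 4-2-1-style hemorrhage count per quadrant
    severe_red_area_px: int = 5000      # DR3 fallback on total red area, 512-px scale
    pdr_mode: bool = False              # experimental confluent-red PDR rule
    pdr_area_px: int = 25000
    collapse_pdr_to_dr3: bool = False

    # --- quality gate (calibrated once on the seeded degradation suite) ---
    fuzzy_min_score: float = 1.0        # Laplacian-energy floor
    dark_max_fraction: float = 0.15
    dark_luminance: float = 40.0
    saturated_max_fraction: float = 0.18
    saturated_level: float = 250.0
    eyelash_max_score: float = 0.004
    decenter_max_px: float = 60.0       # at 512 px scale

    # --- quantification ---
    count_ma_in_hemorrhage_family: bool = True

    # --- synthetic cohort ---
    cohort_sizes: tuple[int, int, int] = (39, 29, 23)

    def scaled(self, value: float, width: int, power: int = 1) -> float:
        """Scale a 512-px-frame parameter to an image of the given width."""
        return value * (width / 512.0) ** power

    def validate(self) -> "RunConfig":
        if self.report_format not in ("csv", "json"):
            raise ConfigurationError(f"report_format must be csv|json, got {self.report_format}")
        if self.color_space != "hsv":
            raise ConfigurationError("only the 'hsv' decomposition is implemented")
        if not (0 < self.roi_min_frac < 1):
            raise ConfigurationError("roi_min_frac must lie in (0, 1)")
        if self.ma_max_area_px <= 0:
            raise ConfigurationError("ma_max_area_px must be positive")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}
_TUPLE_FIELDS = {
    f.name for f in dataclasses.fields(RunConfig) if "tuple" in str(f.type)
}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from defaults, an optional YAML file and
    keyword overrides (later sources win).  Unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    unknown = set(data) - _FIELDS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(data):
        data[key] = tuple(data[key])
    return RunConfig(**data).validate()


def save_config(config: RunConfig, path: str | Path) -> None:
    d = config.to_dict()
    for key in _TUPLE_FIELDS:
        d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")
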