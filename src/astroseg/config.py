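"""Pipeline configuration: validated parameters and flat key=value files."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline.

    Detection parameters are per channel (cell vs mito); hierarchy
    thresholds are in pixels with optional physical scaling through
    ``pixel_size``.  A single ``seed`` drives every source of randomness.
    """

    cell_channel: int = 0
    mito_channel: int = 1
    alpha_cell: float = 1e-3
    min_area_cell: int = 50
    max_area_cell: int = 0  # 0 = unlimited
    alpha_mito: float = 1e-3
    min_area_mito: int = 5
    max_area_mito: int = 400
    ring_width: int = 2
    connectivity: int = 1
    min_link_weight: float = -1.0  # < 0 = automatic (half mean fragment intensity)
    envelope: int = 50
    mask_fill_sigma: float = 2.0  # hysteresis mask completion; 0 disables
    theta_soma: float = 0.6
    theta_primary: float = 0.35
    theta_fine: float = 3.0
    l_tip: int = 5
    spur_len: int = 3
    pixel_size: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha_cell < 1 or not 0 < self.alpha_mito < 1:
            raise ValueError("alpha values must lie in (0, 1)")
        if self.min_area_cell < 1 or self.min_area_mito < 1:
            raise ValueError("min areas must be >= 1")
        if self.ring_width < 1:
            raise ValueError("ring_width must be >= 1")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
        if not 0 < self.theta_soma <= 1 or not 0 < self.theta_primary <= 1:
            raise ValueError("theta_soma and theta_primary must lie in (0, 1]")
        if self.theta_fine <= 0 or self.l_tip < 1 or self.pixel_size <= 0:
            raise ValueError("theta_fine, l_tip and pixel_size must be positive")
        if self.cell_channel < 0 or self.mito_channel < 0:
            raise ValueError("channel indices are 0-based and non-negative")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; unknown keys reject."""
        kinds = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in kinds:
                    raise ValueError(f"{path}:{lineno}: unknown config key '{key}'")
                kwargs[key] = casts.get(kinds[key], float)(val)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in asdict(self).items():
                fh.write(f"{key} = {val}\n")
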