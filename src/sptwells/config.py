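"""Pipeline configuration: schema-validated, unknown keys rejected.

The YAML config mirrors the analysis stages; parameter names used in the
literature on this method (ellPerc, ringMinPts, locGridDx, ratMaxDist,
maxClustNpts, vth) map one-to-one onto the snake_case fields here.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputBlock(_Strict):
    path: Optional[str] = None
    format: Literal["csv", "trackmate_csv"] = "csv"
    dt: Optional[float] = None
    unit: Literal["um", "nm"] = "um"


class MapsBlock(_Strict):
    density_dx: float = 0.05
    smooth_kernel: int = 3
    dx: float = 0.08
    min_disp: int = 15
    cosine: bool = True
    r_filt: float = 0.1
    scale_factor: float = 2.0  # lsc: fine grid is dx / scale_factor


class WellsBlock(_Strict):
    algo: Literal["hybrid", "density", "drift"] = "hybrid"
    multiscale: bool = False
    d_pct: float = 1.0
    dx: float = 0.08
    dx_min: float = 0.05
    dx_step: float = 0.05
    dx_max: float = 0.2
    max_size: float = 1.0
    ell_perc: float = 95.0
    ring_min_pts: int = 10
    e_max: float = 10.0
    llr_min: float = 20.0
    alphas: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    loc_grid_dx: float = 0.02
    dr: float = 0.02
    r_min: float = 0.06
    r_max: float = 0.5
    rat_max_dist: float = 0.3
    w_max: float = 1.0


class TimelapseBlock(_Strict):
    window: float = 20.0
    overlap: float = 0.0
    match_dist: float = 0.2
    bridge: bool = True
    max_gap: int = 1


class GraphBlock(_Strict):
    v_th: Optional[float] = None
    radii: tuple[float, ...] = (0.15, 0.10, 0.06)
    min_counts: tuple[int, ...] = (10, 20, 40)
    max_clust_npts: int = 1000
    boundary_mode: Literal["ellipsoid", "hull"] = "hull"
    min_count: int = 1


class LysoBlock(_Strict):
    coarse_dx: float = 0.48
    top_pct: float = 5.0
    fine_dx: float = 0.2
    level: float = 0.8
    n_nh: int = 10
    r_nh: float = 0.3
    max_gap_frames: int = 2


class SimulateBlock(_Strict):
    kind: Literal["well", "confined", "graph", "switching"] = "well"
    dt_obs: float = 0.02
    n_traj: int = 200
    traj_len: int = 100
    loc_noise: float = 0.0
    # well
    a: float = 0.15
    b: float = 0.15
    phi: float = 0.0
    A: float = 0.4
    D: float = 0.1
    # confined
    domain: tuple[float, float, float, float] = (0.0, 0.0, 2.0, 2.0)
    # optional reflecting region embedding the well (None: start inside the well)
    well_domain: Optional[tuple[float, float, float, float]] = None
    # graph
    graph_kind: Literal["two_node", "triangle", "lattice"] = "triangle"
    node_dwell_bias: float = 5.0
    # switching
    v_fast: float = 1.0
    rate_on: float = 0.5
    rate_off: float = 0.2


class PipelineConfig(_Strict):
    input: InputBlock = Field(default_factory=InputBlock)
    stages: tuple[str, ...] = ("maps", "wells")
    seed: int = 0
    maps: MapsBlock = Field(default_factory=MapsBlock)
    wells: WellsBlock = Field(default_factory=WellsBlock)
    timelapse: TimelapseBlock = Field(default_factory=TimelapseBlock)
    graph: GraphBlock = Field(default_factory=GraphBlock)
    lyso: LysoBlock = Field(default_factory=LysoBlock)
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)
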