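"""Model configuration.

All quantities carry explicit units: lengths in µm, times in h, velocities
in µm/h, accelerations (force per unit effective mass) in µm/h², densities
in µm⁻².

The default parameter triple (alpha, beta, tau) = (1.42 h⁻¹, 38 h⁻¹, 1.40 h)
is the reference fit for MDCK monolayers; sigma0 is calibrated so that the
bulk mean cell speed is about 15 µm/h (see ``fitting.calibrate_sigma``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .geometry import Box, PERIODIC

# reference cell density: 4000 cells per mm², i.e. mean spacing ~17 µm
D0_DEFAULT = 4.0e-3  # µm⁻²

# sigma0 giving a ~15 µm/h bulk mean speed at the default triple
# (lattice closed-form calibration; see docs/methods.md)
SIGMA0_DEFAULT = 490.0  # µm·h⁻²


@dataclass(frozen=True)
class PotentialParams:
    """Pair potential: gaussian repulsive core + Heaviside-gated linear attraction."""

    A_rep: float = 150.0  # µm·h⁻², repulsive force scale
    r_rep: float = 5.0    # µm, gaussian core width
    A_att: float = 2.0    # µm·h⁻², attraction at the cutoff
    r_att: float = 25.0   # µm, onset of attraction
    r_cut: float = 50.0   # µm, interaction cutoff
    r_cap: float = 0.5    # µm, below this the force magnitude is capped

    def __post_init__(self) -> None:
        if not (0 < self.r_rep and 0 < self.r_att <= self.r_cut):
            raise ValueError("require 0 < r_rep and 0 < r_att <= r_cut")
        if self.r_rep >= self.r_att:
            raise ValueError("require r_rep < r_att")
        if self.A_rep < 0 or self.A_att < 0:
            raise ValueError("force amplitudes must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Bulk-dynamics parameters (velocity Langevin equation with OU drive)."""

    alpha: float = 1.42        # h⁻¹, velocity damping rate
    beta: float = 38.0         # h⁻¹, alignment coupling per neighbor
    tau: float = 1.40          # h, OU noise correlation time
    sigma0: float = SIGMA0_DEFAULT  # µm·h⁻², base noise amplitude
    density_noise: bool = False     # noise amplitude grows at low density
    # kappa = 1 doubles the noise amplitude for fully isolated cells; chosen
    # so the unrestrained border advances at a leader-comparable speed while
    # the bulk is unaffected
    kappa: float = 1.0              # dimensionless shape of sigma(d)
    d0: float = D0_DEFAULT          # µm⁻², reference/initial cell density
    potential: PotentialParams = field(default_factory=PotentialParams)
    neighbor_cutoff: float = 100.0  # µm, sector neighbor cutoff
    box: Box = field(default_factory=lambda: Box(1000.0, 1000.0, PERIODIC))
    # explicit Euler stability: the stiffest velocity mode relaxes at
    # alpha + 9*beta (~343 h⁻¹ at defaults), so dt must stay below ~2/343
    dt: float = 0.002          # h, integration step
    seed: int = 0
    graph_refresh_every: int = 1
    symmetrize_graph: bool = False
    align_mean: bool = False   # mean over neighbors instead of plain sum

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.neighbor_cutoff <= 0:
            raise ValueError("neighbor_cutoff must be positive")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.graph_refresh_every < 1:
            raise ValueError("graph_refresh_every must be >= 1")
        if self.potential.r_cut > self.neighbor_cutoff:
            raise ValueError("require r_cut <= neighbor_cutoff")

    def replace(self, **kw) -> "SimConfig":
        d = asdict(self)
        d["potential"] = self.potential
        d["box"] = self.box
        if "potential" in kw and isinstance(kw["potential"], dict):
            kw["potential"] = PotentialParams(**kw["potential"])
        if "box" in kw and isinstance(kw["box"], dict):
            kw["box"] = Box(**kw["box"])
        d.update(kw)
        return SimConfig(**d)


@dataclass(frozen=True)
class LeaderParams:
    """Leader-cell creation and feedback rules at the epithelium border."""

    rate_early: float = 0.3    # mm⁻¹·h⁻¹, creation rate before switch_time
    rate_late: float = 0.1     # mm⁻¹·h⁻¹, creation rate afterwards
    switch_time: float = 20.0  # h
    creation_depth: float = 30.0   # µm, depth behind border eligible
    exclusion_dy: float = 150.0    # µm, lateral exclusion between leaders
    v_mean: float = 18.0       # µm/h, mean initial leader speed
    v_sd: float = 4.0          # µm/h
    min_followers: int = 4     # neighbor count keeping the leader on track
    v_cap: float | None = None  # µm/h; None -> each leader's initial modulus

    def __post_init__(self) -> None:
        if self.rate_early < 0 or self.rate_late < 0:
            raise ValueError("rates must be non-negative")
        if self.v_mean <= 0:
            raise ValueError("v_mean must be positive")
        if self.min_followers < 1:
            raise ValueError("min_followers must be >= 1")


@dataclass(frozen=True)
class DivisionParams:
    T_div: float = 20.0          # h, cell doubling time
    daughter_offset: float = 2.0  # µm
    density_cap: float = D0_DEFAULT  # µm⁻²; divisions must not exceed this

    def __post_init__(self) -> None:
        if self.T_div <= 0:
            raise ValueError("T_div must be positive")


@dataclass(frozen=True)
class SurfaceParams:
    """Free-surface particles: repulsion kernel and damage dynamics."""

    tau_w: float = 1.0            # h, damage relaxation time (inf -> pure accumulation)
    # the wall must rival the propulsive force scale sigma0 (~490 µm·h⁻²),
    # otherwise noise excursions walk cells through intact surface
    A_surf_normal: float = 300.0  # µm·h⁻², repulsion amplitude on normal cells
    r_surf: float = 10.0          # µm, gaussian kernel width (normal cells)
    A_surf_leader: float = 15000.0  # µm·h⁻², damage amplitude from leaders
    # a leader's damage kernel is wide enough to clear a corridor that a
    # 2-3 cell wide finger can follow through
    r_surf_leader: float = 25.0   # µm
    interaction_radius: float = 30.0  # µm, damage summation radius
    # erosion by normal cells requires several stalled cells pressing at
    # once (each contributes its ~sigma-scale driving force); leaders clear
    # a particle within minutes
    w_threshold: float = 600.0    # µm·h⁻¹; 2·tau_w·A_surf_normal
    grid_spacing: float = 10.0    # µm

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0 or self.r_surf <= 0 or self.r_surf_leader <= 0:
            raise ValueError("lengths must be positive")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive (use math.inf for no leak)")
        if self.w_threshold <= 0:
            raise ValueError("w_threshold must be positive")


@dataclass(frozen=True)
class BandParams:
    """Band geometry and frontier bookkeeping for border-progression runs."""

    band_width_x: float = 500.0   # µm, initial epithelium depth
    free_width_x: float = 500.0   # µm, unexplored surface depth
    border_band: float = 20.0     # µm, y-band width for border detection
    leaders: LeaderParams = field(default_factory=LeaderParams)
    division: DivisionParams = field(default_factory=DivisionParams)
    surface: SurfaceParams = field(default_factory=SurfaceParams)
    enable_leaders: bool = True
    enable_division: bool = True
    enable_surface: bool = True
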