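"""Default parameter set for a typical simulated cell.

Units are fixed throughout the package: micrometre (um) for length, second (s)
for time, nanonewton (nN) for force, nanogram (ng) for mass.  Spring constants
are nN/um, viscosities and drag coefficients nN*s/um, pressures nN/um (2D:
force per unit boundary length).

The values below are package defaults chosen to represent a generic epithelial
cell at the stiffness/viscosity ratios used by spring-dashpot cell models;
every scenario exposes them for override.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class CellParams:
    """Mechanical and behavioural constants of one cell (all overridable)."""

    # geometry
    n_points: int = 40          # membrane (= nucleus) nodes per ring
    radius: float = 7.5         # um, free-cell membrane radius
    nucleus_radius: float = 3.0  # um

    # spring constants, nN/um
    k_radial: float = 1.0       # cytoskeleton (membrane <-> nucleus)
    k_chord: float = 2.0        # nucleoskeleton diametral chords
    k_membrane: float = 2.0     # cortical membrane ring
    k_nuc_membrane: float = 4.0  # nuclear membrane ring

    # dashpot viscosities, nN*s/um
    eta_radial: float = 0.1
    eta_chord: float = 0.1
    eta_membrane: float = 0.1
    eta_nuc_membrane: float = 0.1

    # point drag coefficients, nN*s/um (substrate fields override membrane drag)
    drag_membrane: float = 0.5
    drag_nucleus: float = 0.2

    # masses, ng (book-kept for fidelity; unused by the overdamped integrator)
    mass_cytoskeleton: float = 1.0
    mass_nucleus: float = 0.25

    # pressures, nN/um
    p_in: float = 0.3

    # adhesion template of this cell (per-cell half-link parameters)
    k_adhesion: float = 6.0
    eta_adhesion: float = 0.1
    L0_adhesion: float = 1.2

    # growth gating (dimensionless volume-region coefficients, 0 < c_s <= c_g)
    c_s: float = 0.90
    c_g: float = 0.95
    tau_g: float = 1.0          # s between growth attempts

    # mitosis
    F_div_n: float = 1.5        # nN per nucleus node, anaphase pulling
    F_div_m: float = 10.0        # nN, contractile-ring pair magnitude
    L_div: float = 7.5          # um, nuclear-centroid separation for abscission

    # apoptosis
    apoptosis_shrink: float = 5.0   # L0 divisor at apoptosis onset
    min_area: float = 25.0          # um^2, reap threshold

    def __post_init__(self) -> None:
        if not (0.0 < self.c_s <= self.c_g):
            raise ValueError(f"require 0 < c_s <= c_g, got c_s={self.c_s}, c_g={self.c_g}")
        if self.n_points < 3:
            raise ValueError("need at least 3 nodes per ring")

    def with_(self, **kw) -> "CellParams":
        return replace(self, **kw)


@dataclass
class AdhesionRule:
    """World-level junction lifecycle constants.

    Bonds form below ``d_a`` and rupture only above ``d_r`` (d_a < d_r:
    hysteresis band).  Short-range elastic repulsion ramps linearly from zero
    at range ``d_rep`` with stiffness ``k_rep``.
    """

    d_a: float = 1.5       # um, creation distance
    d_r: float = 3.0       # um, rupture distance
    d_rep: float = 1.2     # um, repulsion range
    k_rep: float = 4.0     # nN/um
    one_bond_per_pair: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.d_a < self.d_r):
            raise ValueError("adhesion hysteresis requires 0 < d_a < d_r")
        if self.d_rep <= 0:
            raise ValueError("d_rep must be positive")


@dataclass
class EcmParams:
    """Chain-of-subunits extracellular matrix constants."""

    k: float = 4.0
    eta: float = 0.2
    drag: float = 5.0
    spacing: float = 1.5        # um between chain nodes
    k_adhesion: float = 2.0     # half-link template for cell-ECM junctions
    eta_adhesion: float = 0.1
    L0_adhesion: float = 1.2


#: reference substrate drag of the 2D-culture mode ("high adhesion intensity")
D0 = 5.0


@dataclass
class WorldConfig:
    p_env: float = 0.0
    adhesion: AdhesionRule = field(default_factory=AdhesionRule)
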