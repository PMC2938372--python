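"""Kelvin-Voigt subunits and the node bookkeeping types.

A Voigt subunit is a linear spring (constant ``k``, rest length ``L0``) in
parallel with a linear dashpot (viscosity ``eta``) joining two nodes.  The
force it exerts on endpoint ``a`` is

    F_a = [k (|r_ab| - L0) + eta (v_ab . u)] u,        u = (r_b - r_a)/|r_ab|

i.e. the dashpot damps the relative velocity component projected on the
element axis, so the force pair is central, exactly antisymmetric and
torque-free.  ``F_b = -F_a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

# ring codes used in node addresses (owner_id, ring, index)
RING_MEMBRANE = 0
RING_NUCLEUS = 1
RING_ECM = 2

RING_NAMES = {RING_MEMBRANE: "membrane", RING_NUCLEUS: "nucleus", RING_ECM: "ecm"}
RING_CODES = {v: k for k, v in RING_NAMES.items()}

NodeRef = Tuple[int, int, int]  # (owner id, ring code, index in ring)

CATEGORIES = (
    "radial",
    "nuclear_chord",
    "membrane",
    "nuclear_membrane",
    "adhesion",
    "ecm_chain",
)

LABELS = ("none", "anterior", "posterior", "apical", "basal", "lateral")
LABEL_CODES = {name: i for i, name in enumerate(LABELS)}


class DegenerateAxisError(ValueError):
    """Coincident element endpoints: the force axis is undefined."""


@dataclass
class Node:
    """A mass/drag-bearing point on a cell membrane, nucleus, or ECM chain."""

    id: NodeRef
    owner: int
    ring: str                   # membrane | nucleus | ecm
    index: int
    position: np.ndarray        # um
    velocity: np.ndarray        # um/s
    mass: float = 0.0           # ng (ring mass share; unused by the integrator)
    drag: float = 1.0           # nN*s/um
    label: str = "none"
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.drag < 0 or self.mass < 0:
            raise ValueError("drag and mass must be non-negative")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.fixed:
            self.velocity = np.zeros(2)


@dataclass
class VoigtElement:
    """Spring-dashpot subunit joining nodes ``a`` and ``b`` (unordered)."""

    a: NodeRef
    b: NodeRef
    k: float                    # nN/um
    eta: float                  # nN*s/um
    L0: float                   # um
    category: str = "membrane"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("spring constant k must be positive")
        if self.eta < 0 or self.L0 < 0:
            raise ValueError("eta and L0 must be non-negative")
        if self.a == self.b:
            raise ValueError("element endpoints must differ")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown element category {self.category!r}")


def voigt_force(elem: VoigtElement, positions, velocities):
    """Force pair (on a, on b) of one subunit, nN.

    ``positions``/``velocities`` map node refs to 2-vectors.  Raises
    :class:`DegenerateAxisError` on coincident endpoints.
    """
    ra = np.asarray(positions[elem.a], dtype=float)
    rb = np.asarray(positions[elem.b], dtype=float)
    va = np.asarray(velocities[elem.a], dtype=float)
    vb = np.asarray(velocities[elem.b], dtype=float)
    d = rb - ra
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        raise DegenerateAxisError("coincident element endpoints")
    u = d / L
    mag = elem.k * (L - elem.L0) + elem.eta * float((vb - va) @ u)
    fa = mag * u
    return fa, -fa


def pair_forces(ra, rb, va, vb, k, eta, L0):
    """Vectorised subunit force on the ``a`` endpoints.

    All inputs are (m, 2) or (m,) arrays; returns (m, 2) forces on ``a``
    (forces on ``b`` are the exact negation).
    """
    d = rb - ra
    L = np.linalg.norm(d, axis=1)
    L = np.where(L < 1e-12, 1e-12, L)
    u = d / L[:, None]
    mag = k * (L - L0)
    if eta is not None:
        mag = mag + eta * np.einsum("ij,ij->i", vb - va, u)
    return mag[:, None] * u


def elastic_pair_forces(ra, rb, k, L0):
    """Spring-only part of :func:`pair_forces` (the engine lumps dashpots
    into endpoint drag; see engine docs)."""
    return pair_forces(ra, rb, None, None, k, None, L0)


def combine_adhesion_params(template_a, template_b):
    """Series (harmonic) combination of two cells' half-link templates.

    An adherens junction is modelled as the two cells' attachment half-links
    in series: k = kA kB/(kA+kB), eta = etaA etaB/(etaA+etaB).  Symmetric in
    its arguments.  ``template_*`` are (k, eta) pairs or objects with
    ``k_adhesion``/``eta_adhesion`` attributes.
    """
    ka, ea = _unpack_template(template_a)
    kb, eb = _unpack_template(template_b)
    if min(ka, kb, ea, eb) <= 0:
        raise ValueError("adhesion template parameters must be positive")
    return ka * kb / (ka + kb), ea * eb / (ea + eb)


def _unpack_template(t):
    if hasattr(t, "k_adhesion"):
        return float(t.k_adhesion), float(t.eta_adhesion)
    k, eta = t
    return float(k), float(eta)
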