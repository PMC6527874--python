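"""Morphology and passive electrical skeleton of the mossy-fiber model.

The hippocampal mossy fiber is idealized as a "pearl chain": a soma, ten thin
axonal cylinders (0.2 μm diameter, 100 μm long) and ten large en passant
boutons (4 μm diameter) alternating along the chain.  This module builds that
morphology, attaches passive membrane parameters and channel densities, and
discretizes everything into an unbranched chain of cylindrical compartments
coupled by axial conductances — the spatial skeleton handed to the solver.

Units follow the conventions of compartmental modelling:

* lengths and diameters in μm, membrane areas in μm²
* specific capacitance Cm in μF cm⁻², specific resistance Rm in Ω cm²
* intracellular resistivity Ri in Ω cm
* conductance densities in mS cm⁻², absolute conductances in μS
* potentials in mV
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentGeometry",
    "PassiveParams",
    "ChannelSpec",
    "Section",
    "CompartmentChain",
    "surface_area",
    "axial_conductance",
    "build_mossy_fiber_model",
    "build_single_cable",
    "infinite_cable_lambda",
]

#: μm² → cm²
UM2_TO_CM2 = 1e-8
#: Ω·cm → Ω·μm
OHM_CM_TO_OHM_UM = 1e4


@dataclass(frozen=True)
class SegmentGeometry:
    """Geometry of a single cylindrical compartment.

    ``axial_position`` is the distance (μm) of the segment *center* from the
    proximal face of the soma, measured along the chain midline.
    """

    length: float
    diameter: float
    kind: str  # soma | axon | bouton
    index_along_chain: int
    axial_position: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"segment length must be > 0, got {self.length}")
        if not self.diameter > 0:
            raise ValueError(f"segment diameter must be > 0, got {self.diameter}")
        if self.kind not in ("soma", "axon", "bouton"):
            raise ValueError(f"unknown segment kind {self.kind!r}")


@dataclass(frozen=True)
class PassiveParams:
    """Uniform passive membrane properties.

    The leak conductance density is derived as 1/Rm and never stored
    separately; ``g_leak_density`` converts it to mS cm⁻².
    """

    cm: float = 1.0        # μF cm⁻²
    rm: float = 10_000.0   # Ω cm²
    ri: float = 110.0      # Ω cm
    e_leak: float = -81.0  # mV

    def __post_init__(self) -> None:
        for name in ("cm", "rm", "ri"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def g_leak_density(self) -> float:
        """Leak conductance density in mS cm⁻² (1000/Rm)."""
        return 1e3 / self.rm

    @property
    def tau_m(self) -> float:
        """Isopotential membrane time constant Rm·Cm in ms."""
        return self.rm * self.cm * 1e-3


@dataclass(frozen=True)
class ChannelSpec:
    """Density/reversal/kinetics triple for one conductance.

    A density of exactly 0 is the representation of a knockout: the membrane
    geometry is untouched, only the conductance is removed.
    """

    channel_id: str            # Na | K | leak
    density: float             # mS cm⁻²
    reversal: float            # mV
    gating_model_id: str = "hh_shifted"

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError(f"channel density must be >= 0, got {self.density}")


@dataclass(frozen=True)
class Section:
    """An undivided morphological section before discretization."""

    name: str
    kind: str
    length: float  # μm
    diameter: float  # μm
    nseg: int


def surface_area(segment: SegmentGeometry) -> float:
    """Lateral cylinder area π·d·L of a segment, in μm².

    Boutons and the soma are represented as cylinders with length equal to
    their diameter, so the same formula applies to every kind.
    """
    return math.pi * segment.diameter * segment.length


def _half_axial_resistance(length: float, diameter: float, ri: float) -> float:
    """Axial resistance (Ω) of half a cylindrical segment.

    r = 4·Ri·(L/2) / (π·d²) with Ri converted from Ω·cm to Ω·μm.
    """
    ri_um = ri * OHM_CM_TO_OHM_UM
    return 4.0 * ri_um * (length / 2.0) / (math.pi * diameter**2)


def axial_conductance(seg_a: SegmentGeometry, seg_b: SegmentGeometry, ri: float) -> float:
    """Coupling conductance (μS) between two adjacent segments.

    Series combination of the two half-segment axial resistances; each side
    uses its own geometry, so the value is symmetric in the argument order.
    """
    r = _half_axial_resistance(seg_a.length, seg_a.diameter, ri) + _half_axial_resistance(
        seg_b.length, seg_b.diameter, ri
    )
    return 1e6 / r


def infinite_cable_lambda(rm: float, diameter: float, ri: float) -> float:
    """DC length constant √(Rm·d/(4·Ri)) of an infinite cable, in μm.

    ``rm`` in Ω cm², ``diameter`` in μm, ``ri`` in Ω cm.  For the 0.2 μm
    mossy-fiber axon with Rm = 10 kΩ cm² and Ri = 110 Ω cm this evaluates to
    ≈ 213 μm; it is an upper bound on the length constant measured in the
    bouton-loaded chain.
    """
    d_cm = diameter * 1e-4
    lam_cm = math.sqrt(rm * d_cm / (4.0 * ri))
    return lam_cm * 1e4


class CompartmentChain:
    """Discretized unbranched chain of compartments.

    Per-segment state is held in flat numpy arrays so the solver can operate
    vectorized.  Both chain ends are sealed (zero axial flux): the coupling
    list simply stops at the first and last segment.

    Attributes
    ----------
    sections : list[Section]
        Ordered morphological sections (soma, axon1, bouton1, ...).
    segments : list[SegmentGeometry]
        One entry per compartment, ordered from the soma outward.
    area : ndarray, μm²
    cm : ndarray, μF cm⁻² (specific, per segment so Cm sweeps can be regional)
    g_leak_density, gna_density, gk_density : ndarray, mS cm⁻²
    e_leak, e_na, e_k : ndarray, mV
    g_axial : ndarray, μS, coupling between segment i and i+1
    """

    def __init__(
        self,
        sections: list[Section],
        passive: PassiveParams,
        na_spec: ChannelSpec,
        k_spec: ChannelSpec,
        soma_na_density: float | None = None,
        gating_model_id: str = "hh_shifted",
        gating_params: dict | None = None,
    ):
        self.sections = list(sections)
        self.passive = passive
        self.na_spec = na_spec
        self.k_spec = k_spec
        self.gating_model_id = gating_model_id
        self.gating_params = dict(gating_params or {})

        segments: list[SegmentGeometry] = []
        section_index: list[int] = []
        x = 0.0
        for si, sec in enumerate(self.sections):
            seg_len = sec.length / sec.nseg
            for _ in range(sec.nseg):
                segments.append(
                    SegmentGeometry(
                        length=seg_len,
                        diameter=sec.diameter,
                        kind=sec.kind,
                        index_along_chain=len(segments),
                        axial_position=x + seg_len / 2.0,
                    )
                )
                section_index.append(si)
                x += seg_len
        self.segments = segments
        self.total_length = x
        self.section_index = np.asarray(section_index, dtype=int)

        n = len(segments)
        self.n = n
        self.length = np.array([s.length for s in segments])
        self.diameter = np.array([s.diameter for s in segments])
        self.kind = np.array([s.kind for s in segments])
        self.x = np.array([s.axial_position for s in segments])
        self.area = np.array([surface_area(s) for s in segments])

        self.cm = np.full(n, passive.cm)
        self.g_leak_density = np.full(n, passive.g_leak_density)
        self.e_leak = np.full(n, passive.e_leak)

        self.gna_density = np.full(n, na_spec.density)
        if soma_na_density is not None:
            self.gna_density[self.kind == "soma"] = soma_na_density
        self.gk_density = np.full(n, k_spec.density)
        self.e_na = np.full(n, na_spec.reversal)
        self.e_k = np.full(n, k_spec.reversal)

        self.g_axial = np.array(
            [
                axial_conductance(segments[i], segments[i + 1], passive.ri)
                for i in range(n - 1)
            ]
        )

    # ------------------------------------------------------------------ sites

    def section_slice(self, name: str) -> slice:
        """Segment index range of a named section."""
        for si, sec in enumerate(self.sections):
            if sec.name == name:
                idx = np.flatnonzero(self.section_index == si)
                return slice(int(idx[0]), int(idx[-1]) + 1)
        raise KeyError(f"no section named {name!r}")

    def section_mask(self, names) -> np.ndarray:
        """Boolean per-segment mask covering a union of whole sections."""
        mask = np.zeros(self.n, dtype=bool)
        for name in names:
            sl = self.section_slice(name)
            mask[sl] = True
        return mask

    def seg_index(self, site: str) -> int:
        """Resolve a site name to a segment index.

        ``"bouton3"`` refers to the center segment of that section;
        ``"axon8:0.25"`` to the segment at fractional position 0.25 along
        section ``axon8``.
        """
        if ":" in site:
            name, frac_s = site.split(":")
            frac = float(frac_s)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fractional site position must be in [0,1]: {site}")
        else:
            name, frac = site, 0.5
        sl = self.section_slice(name)
        nseg = sl.stop - sl.start
        k = min(nseg - 1, int(frac * nseg))
        return sl.start + k

    def site_position(self, site: str) -> float:
        """Axial position (μm from soma proximal face) of a named site."""
        return float(self.x[self.seg_index(site)])

    def section_end(self, name: str) -> float:
        """Axial position of the distal face of a named section."""
        sl = self.section_slice(name)
        i = sl.stop - 1
        return float(self.x[i] + self.length[i] / 2.0)

    def section_names(self) -> list[str]:
        return [s.name for s in self.sections]

    # ------------------------------------------------------------- utilities

    def copy(self) -> "CompartmentChain":
        """Deep copy; modifiers mutate copies, never the base model."""
        return copy.deepcopy(self)

    def capacitance_nF(self) -> np.ndarray:
        """Absolute membrane capacitance per segment in nF."""
        return self.cm * self.area * UM2_TO_CM2 * 1e3

    def conductance_uS(self, density: np.ndarray) -> np.ndarray:
        """Convert a per-segment density (mS cm⁻²) to absolute μS."""
        return density * self.area * UM2_TO_CM2 * 1e3

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CompartmentChain({len(self.sections)} sections, {self.n} segments, "
            f"{self.total_length:.0f} μm)"
        )


def _nseg_for(length: float, nseg_per_um: float) -> int:
    """Segments for a section at the requested density, at least one."""
    return max(1, round(length * nseg_per_um))


def build_mossy_fiber_model(
    n_boutons: int = 10,
    soma_diameter: float = 10.0,
    axon_diameter: float = 0.2,
    axon_length: float = 100.0,
    bouton_diameter: float = 4.0,
    passive: PassiveParams | None = None,
    gna_axon: float = 50.0,
    gna_soma: float = 10.0,
    gk: float = 36.0,
    e_na: float = 50.0,
    e_k: float = -85.0,
    nseg_per_um: float = 1.0,
    gating_model_id: str = "hh_shifted",
    gating_params: dict | None = None,
) -> CompartmentChain:
    """Build the default pearl-chain mossy-fiber model.

    The chain is ordered soma → axon1 → bouton1 → … → axon10 → bouton10, with
    the soma attached to the first axonal cylinder.  Soma and boutons are
    represented as cylinders with length equal to their diameter, which
    preserves the lateral surface area the model exposes to the solver.

    Default parameter values: Cm = 1 μF cm⁻², Rm = 10 kΩ cm², Ri = 110 Ω cm,
    g_Na = 50 mS cm⁻² on axon and boutons (10 on the soma), g_K = 36 mS cm⁻²
    everywhere, E_Na = +50 mV, E_K = −85 mV, E_leak = −81 mV; 1 segment per μm.
    """
    if n_boutons < 0:
        raise ValueError("n_boutons must be >= 0")
    passive = passive or PassiveParams()
    for nm, v in (
        ("soma_diameter", soma_diameter),
        ("axon_diameter", axon_diameter),
        ("axon_length", axon_length),
        ("bouton_diameter", bouton_diameter),
    ):
        if not v > 0:
            raise ValueError(f"{nm} must be positive, got {v}")

    sections = [Section("soma", "soma", soma_diameter, soma_diameter, _nseg_for(soma_diameter, nseg_per_um))]
    for k in range(1, n_boutons + 1):
        sections.append(
            Section(f"axon{k}", "axon", axon_length, axon_diameter, _nseg_for(axon_length, nseg_per_um))
        )
        sections.append(
            Section(
                f"bouton{k}", "bouton", bouton_diameter, bouton_diameter,
                _nseg_for(bouton_diameter, nseg_per_um),
            )
        )

    na_spec = ChannelSpec("Na", gna_axon, e_na, gating_model_id)
    k_spec = ChannelSpec("K", gk, e_k, gating_model_id)
    return CompartmentChain(
        sections,
        passive,
        na_spec,
        k_spec,
        soma_na_density=gna_soma,
        gating_model_id=gating_model_id,
        gating_params=gating_params,
    )


def build_single_cable(
    length: float = 500.0,
    diameter: float = 1.0,
    passive: PassiveParams | None = None,
    gna: float = 0.0,
    gk: float = 0.0,
    e_na: float = 50.0,
    e_k: float = -85.0,
    nseg_per_um: float = 1.0,
    gating_model_id: str = "hh_shifted",
) -> CompartmentChain:
    """Single uniform cylinder with sealed ends (no soma, no boutons).

    The degenerate chain used by analytic cable tests; passive by default.
    """
    passive = passive or PassiveParams()
    sections = [Section("cable", "axon", length, diameter, _nseg_for(length, nseg_per_um))]
    na_spec = ChannelSpec("Na", gna, e_na, gating_model_id)
    k_spec = ChannelSpec("K", gk, e_k, gating_model_id)
    return CompartmentChain(sections, passive, na_spec, k_spec, gating_model_id=gating_model_id)
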