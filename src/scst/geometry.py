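"""Parametric geometric models of stereotypic tissues and their positional addresses.

The central object is a "corn plot" coordinate system for a cup-shaped,
layered structure (the gastrula-stage embryo being the motivating case):
the proximal-distal axis is divided into unit-thickness sections, each
section carries concentric germ-layer rings (epiblast/ectoderm innermost,
mesoderm, endoderm outermost), and each ring is divided into named angular
sectors.  A sampling position ("positional address") is a
(section, sector, layer) triple with a representative 3D coordinate on its
ring, and an associated interior region (an annular wedge) used for
single-cell placement.

Conventions: anterior lies on the negative x-axis, posterior on the
positive x-axis, the right side of the body on positive y; section ``s``
is centred at ``z = s`` and spans ``z in (s - 0.5, s + 0.5)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LAYERS",
    "EmbryoModelConfig",
    "GermLayerGeometry",
    "PositionalAddress",
    "PositionRegion",
    "GeometryError",
    "AddressError",
    "build_geometry",
    "address_coordinates",
    "region_for_address",
    "expanded_layer_regions",
    "enumerate_addresses",
    "example_e75_config",
    "example_cht_config",
    "half_oval_surface",
]

#: Germ layers ordered innermost to outermost.
LAYERS = ("ectoderm", "mesoderm", "endoderm")

_TWO_PI = 2.0 * math.pi


class GeometryError(ValueError):
    """Raised for invalid geometry configurations."""


class AddressError(KeyError):
    """Raised for unknown sections, sectors or layers."""


def _wrap_angle(theta: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    theta = math.fmod(theta, _TWO_PI)
    if theta > math.pi:
        theta -= _TWO_PI
    elif theta <= -math.pi:
        theta += _TWO_PI
    return theta


@dataclass(frozen=True)
class EmbryoModelConfig:
    """Parameters of the layered half-oval ("corn plot") tissue model.

    Parameters
    ----------
    stage:
        Stage label, e.g. ``"E7.5"``.
    proximal_distal_length:
        Length of the proximal-distal axis (L_P-D), in model length units.
        Sections are unit thickness, so this usually equals ``n_sections``.
    n_sections:
        Number of cross-sections along the proximal-distal axis,
        numbered 1..n; section ``s`` is centred at ``z = s``.
    layer_diameters:
        Anterior-posterior diameter of each germ-layer ring
        (L_A-P per layer); the ring radius is half the diameter.
    sector_schemes:
        Per layer, the ordered ``(label, nominal_angle)`` pairs of its
        angular sectors; angles in radians in the (x, y) plane
        (posterior = 0, anterior = pi, right side = +pi/2).
    layer_sections:
        Optional inclusive ``(first, last)`` section range per layer;
        defaults to the full 1..n_sections range.
    placement_radii:
        Optional per-layer override of the radius at which addresses are
        placed.  Defaults to the derived layer radius; published address
        tables that use a different ring radius are loaded through this.
    pole_addresses:
        Degenerate on-axis positions, as ``(layer, section, label)``
        triples; their coordinate is (0, 0, z) and their region the full
        disc of the layer at that section.
    ectoderm_inner_radius:
        Inner radius of the innermost (ectoderm) ring region.  When None,
        the inter-layer ratio is continued one step inward
        (``r_ect**2 / r_mes``).
    anterior_axis_sign:
        -1 (default) places anterior on negative x, +1 mirrors the model.
    """

    stage: str
    proximal_distal_length: float
    n_sections: int
    layer_diameters: Mapping[str, float]
    sector_schemes: Mapping[str, Sequence[tuple[str, float]]]
    layer_sections: Mapping[str, tuple[int, int]] | None = None
    placement_radii: Mapping[str, float] | None = None
    pole_addresses: Sequence[tuple[str, int, str]] = ()
    ectoderm_inner_radius: float | None = None
    anterior_axis_sign: int = -1

    def __post_init__(self) -> None:
        if self.proximal_distal_length <= 0:
            raise GeometryError("proximal_distal_length must be > 0")
        if self.n_sections < 1:
            raise GeometryError("n_sections must be >= 1")
        if self.anterior_axis_sign not in (-1, 1):
            raise GeometryError("anterior_axis_sign must be -1 or +1")
        for layer, diam in self.layer_diameters.items():
            if diam <= 0:
                raise GeometryError(f"diameter of layer {layer!r} must be > 0")
        for layer, scheme in self.sector_schemes.items():
            angles = [_wrap_angle(a) for _, a in scheme]
            if len(set(np.round(angles, 12))) != len(angles):
                raise GeometryError(f"duplicate sector angles in layer {layer!r}")
            labels = [lab for lab, _ in scheme]
            if len(set(labels)) != len(labels):
                raise GeometryError(f"duplicate sector labels in layer {layer!r}")

    @classmethod
    def from_ratios(
        cls,
        stage: str,
        proximal_distal_length: float,
        outer_diameter: float,
        end_mes_ratio: float,
        mes_ect_ratio: float,
        n_sections: int,
        sector_schemes: Mapping[str, Sequence[tuple[str, float]]],
        **kwargs,
    ) -> "EmbryoModelConfig":
        """Build a config from the outermost diameter and inter-layer ratios.

        ``end_mes_ratio`` and ``mes_ect_ratio`` are the diameter ratios
        endoderm/mesoderm and mesoderm/ectoderm; both must exceed 0 and,
        for a properly nested model, be > 1.
        """
        if end_mes_ratio <= 0 or mes_ect_ratio <= 0:
            raise GeometryError("layer ratios must be > 0")
        diameters = {
            "endoderm": outer_diameter,
            "mesoderm": outer_diameter / end_mes_ratio,
            "ectoderm": outer_diameter / end_mes_ratio / mes_ect_ratio,
        }
        return cls(
            stage=stage,
            proximal_distal_length=proximal_distal_length,
            n_sections=n_sections,
            layer_diameters=diameters,
            sector_schemes=sector_schemes,
            **kwargs,
        )

    def sections_for_layer(self, layer: str) -> range:
        if self.layer_sections and layer in self.layer_sections:
            lo, hi = self.layer_sections[layer]
        else:
            lo, hi = 1, self.n_sections
        return range(lo, hi + 1)

    def to_json(self) -> str:
        doc = {
            "stage": self.stage,
            "proximal_distal_length": self.proximal_distal_length,
            "n_sections": self.n_sections,
            "layer_diameters": dict(self.layer_diameters),
            "sector_schemes": {
                layer: [[lab, ang] for lab, ang in scheme]
                for layer, scheme in self.sector_schemes.items()
            },
            "layer_sections": dict(self.layer_sections) if self.layer_sections else None,
            "placement_radii": dict(self.placement_radii) if self.placement_radii else None,
            "pole_addresses": [list(p) for p in self.pole_addresses],
            "ectoderm_inner_radius": self.ectoderm_inner_radius,
            "anterior_axis_sign": self.anterior_axis_sign,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EmbryoModelConfig":
        doc = json.loads(text)
        return cls(
            stage=doc["stage"],
            proximal_distal_length=doc["proximal_distal_length"],
            n_sections=doc["n_sections"],
            layer_diameters=doc["layer_diameters"],
            sector_schemes={
                layer: [tuple(pair) for pair in scheme]
                for layer, scheme in doc["sector_schemes"].items()
            },
            layer_sections={k: tuple(v) for k, v in doc["layer_sections"].items()}
            if doc.get("layer_sections")
            else None,
            placement_radii=doc.get("placement_radii") or None,
            pole_addresses=tuple(tuple(p) for p in doc.get("pole_addresses", ())),
            ectoderm_inner_radius=doc.get("ectoderm_inner_radius"),
            anterior_axis_sign=doc.get("anterior_axis_sign", -1),
        )


@dataclass(frozen=True)
class GermLayerGeometry:
    """Derived per-layer ring radii for a config.

    ``radii`` are half the per-layer A-P diameters; ``placement_radii``
    are the radii at which positional addresses are placed (equal to
    ``radii`` unless overridden in the config).
    """

    config: EmbryoModelConfig
    radii: Mapping[str, float]
    placement_radii: Mapping[str, float]

    def inner_radius(self, layer: str) -> float:
        """Inner boundary of a layer's annular region."""
        order = [l for l in LAYERS if l in self.radii]
        i = order.index(layer)
        if i > 0:
            return self.radii[order[i - 1]]
        cfg = self.config
        if cfg.ectoderm_inner_radius is not None:
            return cfg.ectoderm_inner_radius
        if len(order) > 1:
            # continue the inter-layer ratio one step inward
            return self.radii[layer] ** 2 / self.radii[order[1]]
        return 0.0


@dataclass(frozen=True)
class PositionalAddress:
    """One sampling position: stage, section, sector, germ layer, coordinate."""

    stage: str
    section: int
    sector: str
    layer: str
    coordinate: tuple[float, float, float]

    @property
    def name(self) -> str:
        return f"{self.section}{self.sector}"

    def __str__(self) -> str:  # pragma: no cover - display helper
        x, y, z = self.coordinate
        return f"{self.name}[{self.layer}] ({x:g}, {y:g}, {z:g})"


@dataclass(frozen=True)
class PositionRegion:
    """An annular-wedge interior region: r in (r_inner, r_outer),
    angle within ``theta_width`` of ``theta_center``, z in (z_lo, z_hi).

    ``theta_width == 2*pi`` denotes a full annulus (or disc if
    ``r_inner == 0``)."""

    r_inner: float
    r_outer: float
    theta_center: float
    theta_width: float
    z_lo: float
    z_hi: float

    def __post_init__(self) -> None:
        if not self.r_inner < self.r_outer:
            raise GeometryError("r_inner must be < r_outer")
        if not self.z_lo < self.z_hi:
            raise GeometryError("z_lo must be < z_hi")
        if not 0.0 < self.theta_width <= _TWO_PI + 1e-12:
            raise GeometryError("angular width must be in (0, 2*pi]")

    @property
    def is_full_circle(self) -> bool:
        return self.theta_width >= _TWO_PI - 1e-12

    def contains(self, point: Sequence[float], tol: float = 1e-9) -> bool:
        x, y, z = point
        if not (self.z_lo - tol <= z <= self.z_hi + tol):
            return False
        r = math.hypot(x, y)
        if not (self.r_inner - tol <= r <= self.r_outer + tol):
            return False
        if self.is_full_circle or r <= tol:
            return True
        dtheta = _wrap_angle(math.atan2(y, x) - self.theta_center)
        return abs(dtheta) <= self.theta_width / 2.0 + tol / max(r, 1e-12)

    def clamp(self, point: Sequence[float]) -> tuple[float, float, float]:
        """Project a point onto the closed region (cylindrical clamping)."""
        x, y, z = point
        z = min(max(z, self.z_lo), self.z_hi)
        r = math.hypot(x, y)
        theta = math.atan2(y, x) if r > 0 else self.theta_center
        r = min(max(r, self.r_inner), self.r_outer)
        if not self.is_full_circle:
            half = self.theta_width / 2.0
            dtheta = _wrap_angle(theta - self.theta_center)
            dtheta = min(max(dtheta, -half), half)
            theta = self.theta_center + dtheta
        return (r * math.cos(theta), r * math.sin(theta), z)

    def centroid(self) -> tuple[float, float, float]:
        r_mid = 0.5 * (self.r_inner + self.r_outer)
        z_mid = 0.5 * (self.z_lo + self.z_hi)
        if self.is_full_circle:
            return (0.0, 0.0, z_mid)
        return (
            r_mid * math.cos(self.theta_center),
            r_mid * math.sin(self.theta_center),
            z_mid,
        )

    def max_chord(self) -> float:
        """Longest straight segment contained in the closed region.

        Computed as the planar maximum chord of the annular wedge combined
        in quadrature with the z-span.
        """
        if self.is_full_circle or self.theta_width >= math.pi:
            planar = 2.0 * self.r_outer
        else:
            a = self.theta_width
            candidates = [
                2.0 * self.r_outer * math.sin(a / 2.0),  # outer corner to outer corner
                self.r_outer - self.r_inner,  # radial span
                math.sqrt(
                    self.r_inner**2
                    + self.r_outer**2
                    - 2.0 * self.r_inner * self.r_outer * math.cos(a)
                ),  # inner corner to opposite outer corner
            ]
            planar = max(candidates)
        return math.hypot(planar, self.z_hi - self.z_lo)

    def max_chord_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of a longest straight segment in the closed region."""
        c, w = self.theta_center, self.theta_width
        if self.is_full_circle or w >= math.pi:
            # a full diameter fits: both endpoints on the outer circle
            theta_a = c if self.is_full_circle else c - w / 2.0
            a1, a2 = (self.r_outer, theta_a), (self.r_outer, theta_a + math.pi)
        else:
            pairs = [
                ((self.r_outer, c - w / 2.0), (self.r_outer, c + w / 2.0)),
                ((self.r_inner, c), (self.r_outer, c)),
                ((self.r_inner, c - w / 2.0), (self.r_outer, c + w / 2.0)),
            ]
            best = max(
                pairs,
                key=lambda pq: (
                    pq[0][0] ** 2 + pq[1][0] ** 2
                    - 2.0 * pq[0][0] * pq[1][0] * math.cos(pq[1][1] - pq[0][1])
                ),
            )
            a1, a2 = best
        p = np.array([a1[0] * math.cos(a1[1]), a1[0] * math.sin(a1[1]), self.z_lo])
        q = np.array([a2[0] * math.cos(a2[1]), a2[0] * math.sin(a2[1]), self.z_hi])
        return p, q

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points i.i.d. uniform over the region volume.

        Radius is drawn from the area-weighted density (sqrt trick on r^2),
        making the draw exactly uniform; no rejection needed for wedges.
        """
        u = rng.random(n)
        r = np.sqrt(self.r_inner**2 + u * (self.r_outer**2 - self.r_inner**2))
        half = self.theta_width / 2.0
        theta = self.theta_center + rng.uniform(-half, half, n)
        z = rng.uniform(self.z_lo, self.z_hi, n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def build_geometry(config: EmbryoModelConfig) -> GermLayerGeometry:
    """Derive per-layer ring radii (half the A-P diameters) from a config."""
    radii = {layer: d / 2.0 for layer, d in config.layer_diameters.items()}
    order = [l for l in LAYERS if l in radii]
    for inner, outer in zip(order, order[1:]):
        if not radii[inner] < radii[outer]:
            raise GeometryError(
                f"layer radii must nest: r_{inner}={radii[inner]} >= r_{outer}={radii[outer]}"
            )
    placement = dict(radii)
    if config.placement_radii:
        placement.update(config.placement_radii)
    return GermLayerGeometry(config=config, radii=radii, placement_radii=placement)


def _find_sector(config: EmbryoModelConfig, sector: str, layer: str | None):
    """Resolve (layer, nominal angle) of a sector label."""
    layers = [layer] if layer is not None else list(config.sector_schemes)
    for lay in layers:
        scheme = config.sector_schemes.get(lay, ())
        for lab, ang in scheme:
            if lab == sector:
                return lay, ang, len(scheme)
    raise AddressError(f"unknown sector {sector!r}" + (f" in layer {layer!r}" if layer else ""))


def address_coordinates(
    config: EmbryoModelConfig,
    section: int,
    sector: str,
    layer: str | None = None,
) -> PositionalAddress:
    """Coordinate of a positional address on its layer ring.

    The address is placed at ``(R cos(theta), R sin(theta), section)``
    where R is the layer's placement radius and ``theta`` the sector's
    nominal angle; the ``anterior_axis_sign`` flag mirrors x.
    """
    for lay, sec, lab in config.pole_addresses:
        if lab == sector and sec == section and (layer is None or lay == layer):
            return PositionalAddress(config.stage, section, sector, lay, (0.0, 0.0, float(section)))
    lay, ang, _ = _find_sector(config, sector, layer)
    if section not in config.sections_for_layer(lay):
        raise AddressError(f"section {section} outside the range of layer {lay!r}")
    geom = build_geometry(config)
    radius = geom.placement_radii[lay]
    x = radius * math.cos(ang)
    y = radius * math.sin(ang)
    if config.anterior_axis_sign == 1:
        x = -x
    # snap near-zero components so midline sectors have exact zeros
    if abs(x) < 1e-12:
        x = 0.0
    if abs(y) < 1e-12:
        y = 0.0
    return PositionalAddress(config.stage, section, sector, lay, (x, y, float(section)))


def region_for_address(config: EmbryoModelConfig, address: PositionalAddress) -> PositionRegion:
    """Interior constraint region of an address.

    The region is the layer's annulus at the address's section, cut to a
    wedge of width ``2*pi / #sectors`` centred on the sector's nominal
    angle; pole addresses get the full layer disc.
    """
    geom = build_geometry(config)
    z_lo, z_hi = address.section - 0.5, address.section + 0.5
    for lay, sec, lab in config.pole_addresses:
        if lab == address.sector and sec == address.section:
            return PositionRegion(0.0, geom.radii[lay], 0.0, _TWO_PI, z_lo, z_hi)
    lay, ang, n_sectors = _find_sector(config, address.sector, address.layer)
    if config.anterior_axis_sign == 1:
        ang = math.pi - ang
    width = _TWO_PI / n_sectors
    r_outer = geom.radii[lay]
    r_inner = geom.inner_radius(lay)
    return PositionRegion(r_inner, r_outer, _wrap_angle(ang), width, z_lo, z_hi)


def expanded_layer_regions(
    config: EmbryoModelConfig,
    layer: str,
    angular_extents: Mapping[int, float],
    origin_angle: float = 0.0,
) -> dict[int, PositionRegion]:
    """Per-section partial annuli for a layer that wraps gradually around
    the structure (the expanding-wings model of the nascent mesoderm).

    ``angular_extents`` maps section -> fraction of the full circle in
    (0, 1]; the partial annulus grows symmetrically from ``origin_angle``
    (posterior by default).  Extent 1 reproduces the full annulus.
    """
    geom = build_geometry(config)
    r_outer = geom.radii[layer]
    r_inner = geom.inner_radius(layer)
    regions: dict[int, PositionRegion] = {}
    for section, extent in angular_extents.items():
        if not 0.0 < extent <= 1.0:
            raise GeometryError(f"angular extent {extent} for section {section} not in (0, 1]")
        regions[section] = PositionRegion(
            r_inner,
            r_outer,
            _wrap_angle(origin_angle),
            extent * _TWO_PI,
            section - 0.5,
            section + 0.5,
        )
    return regions


def enumerate_addresses(config: EmbryoModelConfig) -> list[PositionalAddress]:
    """All positional addresses of a config, poles first within their
    section, ordered by section, then layer (innermost out), then scheme
    order."""
    out: list[PositionalAddress] = []
    pole_by_section: dict[int, list[tuple[str, int, str]]] = {}
    for pole in config.pole_addresses:
        pole_by_section.setdefault(pole[1], []).append(pole)
    max_section = config.n_sections
    for section in range(1, max_section + 1):
        for lay, sec, lab in pole_by_section.get(section, ()):
            out.append(address_coordinates(config, section, lab, lay))
        for lay in LAYERS:
            if lay not in config.sector_schemes:
                continue
            if section not in config.sections_for_layer(lay):
                continue
            for lab, _ in config.sector_schemes[lay]:
                out.append(address_coordinates(config, section, lab, lay))
    return out


def half_oval_surface(
    config: EmbryoModelConfig, layer: str, n_u: int = 48, n_v: int = 24
) -> np.ndarray:
    """Points on the axis-scaled hemispherical rendering surface of a layer.

    The surface is ``x**2 + y**2 + (z * L_A-P / (2 * L_P-D))**2 = r**2``
    with z measured distally from the proximal rim; rendering only, no
    positional address depends on it.
    """
    r = build_geometry(config).radii[layer]
    scale = config.layer_diameters[layer] / (2.0 * config.proximal_distal_length)
    theta = np.linspace(0.0, _TWO_PI, n_u)
    phi = np.linspace(0.0, math.pi / 2.0, n_v)
    T, P = np.meshgrid(theta, phi)
    x = r * np.cos(P) * np.cos(T)
    y = r * np.cos(P) * np.sin(T)
    z = config.proximal_distal_length - r * np.sin(P) / scale
    return np.stack([x, y, z], axis=-1)


def _hex_scheme() -> list[tuple[str, float]]:
    """Six epiblast sectors at multiples of pi/3 (posterior at 0)."""
    return [
        ("P", 0.0),
        ("R2", math.pi / 3.0),
        ("R1", 2.0 * math.pi / 3.0),
        ("A", math.pi),
        ("L1", -2.0 * math.pi / 3.0),
        ("L2", -math.pi / 3.0),
    ]


def example_e75_config() -> EmbryoModelConfig:
    """Bundled late-gastrula (E7.5) mouse embryo model.

    Derived from the published model parameters (proximal-distal length 9,
    outer A-P diameter 9, inter-layer diameter ratios 1.2); the epiblast
    ring is placed at the published radius 3.  The sector scheme is a
    reconstruction (six epiblast sectors, anterior/posterior mesoderm and
    endoderm, one distal pole position) giving the published 81 sampling
    positions; it is fully overridable.
    """
    return EmbryoModelConfig.from_ratios(
        stage="E7.5",
        proximal_distal_length=9.0,
        outer_diameter=9.0,
        end_mes_ratio=1.2,
        mes_ect_ratio=1.2,
        n_sections=9,
        sector_schemes={
            "ectoderm": _hex_scheme(),
            "mesoderm": [("MP", 0.0), ("MA", math.pi)],
            "endoderm": [("EP", 0.0), ("EA", math.pi)],
        },
        layer_sections={
            "ectoderm": (2, 9),
            "mesoderm": (2, 9),
            "endoderm": (2, 9),
        },
        placement_radii={"ectoderm": 3.0},
        pole_addresses=(("ectoderm", 1, "T"),),
    )


def example_cht_config() -> EmbryoModelConfig:
    """Bundled single-layer six-region scheme for an elongated niche
    tissue (modelled on the zebrafish caudal hematopoietic tissue): one
    'layer', six sections, one sector per section ring."""
    return EmbryoModelConfig(
        stage="CHT",
        proximal_distal_length=6.0,
        n_sections=6,
        layer_diameters={"ectoderm": 2.0},
        sector_schemes={"ectoderm": [("C", 0.0)]},
        ectoderm_inner_radius=0.0,
    )
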