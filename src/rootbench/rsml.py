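"""RSML serialization and ground-truth trait extraction.

RSML (Root System Markup Language) is an XML interchange format for root
architectures: a ``scene`` holds ``plant`` elements whose ``root`` elements
nest to encode topology, each carrying a polyline geometry and per-node
property functions (here: diameter).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from rootbench.config import DEFAULT_DIAMETER_MM
from rootbench.simulator import Root, RootSystem

#: The thirteen ground-truth traits, in canonical column order.
TRAIT_COLUMNS = [
    "tot_root_length",
    "tot_1_order_length",
    "tot_2plus_order_length",
    "mean_1_order_length",
    "mean_2plus_order_length",
    "n_1_orders",
    "n_2plus_orders",
    "mean_2plus_order_density",
    "mean_1_order_diam",
    "mean_2plus_order_diam",
    "mean_2plus_order_angle",
    "width",
    "depth",
]

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0, "um": 1e-3, "inch": 25.4}


@dataclass
class GroundTruthRecord:
    """The ground-truth morphology of one root system.

    Lengths, diameters, width and depth are in mm, the lateral density in
    mm⁻¹ and the insertion angle in degrees; means over empty sets (systems
    without laterals) are NaN.
    """

    tot_root_length: float
    tot_1_order_length: float
    tot_2plus_order_length: float
    mean_1_order_length: float
    mean_2plus_order_length: float
    n_1_orders: int
    n_2plus_orders: int
    mean_2plus_order_density: float
    mean_1_order_diam: float
    mean_2plus_order_diam: float
    mean_2plus_order_angle: float
    width: float
    depth: float
    plant_type: str

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Writing

def _fmt(v: float) -> str:
    return repr(float(v))


def _root_element(root: Root, index: int) -> etree._Element:
    el = etree.Element("root", ID=str(index), label=f"order_{root.order}")
    props = etree.SubElement(el, "properties")
    ins = etree.SubElement(props, "insertion_position")
    ins.set("unit", "mm")
    ins.set("value", _fmt(root.insertion_position_mm))
    geom = etree.SubElement(el, "geometry")
    poly = etree.SubElement(geom, "polyline")
    for x, y in zip(root.xs, root.ys):
        etree.SubElement(poly, "point", x=_fmt(x), y=_fmt(y))
    fns = etree.SubElement(el, "functions")
    fn = etree.SubElement(fns, "function", name="diameter", domain="polyline")
    for d in root.diams:
        etree.SubElement(fn, "sample", value=_fmt(d))
    return el


def write_rsml(system: RootSystem, destination: str | Path) -> None:
    """Serialize a root system to an RSML file (mm units, y-down).

    Identical systems produce byte-identical files, so seeded simulations
    round-trip reproducibly.
    """
    system.validate()
    if not system.roots:
        raise ValueError("cannot serialize an empty root system")

    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "mm"
    etree.SubElement(meta, "resolution").text = "1"
    etree.SubElement(meta, "software").text = "rootbench"
    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant", id="1", label=system.plant_type)

    counter = [0]

    def attach(parent_el: etree._Element, root: Root) -> None:
        counter[0] += 1
        el = _root_element(root, counter[0])
        parent_el.append(el)
        for child in sorted(root.children, key=lambda c: c.insertion_position_mm):
            attach(el, child)

    for axis in system.axes:
        attach(plant, axis)

    tree = etree.ElementTree(rsml)
    try:
        tree.write(str(destination), xml_declaration=True, encoding="UTF-8",
                   pretty_print=True)
    except OSError as exc:
        raise OSError(f"cannot write RSML to {destination}: {exc}") from exc


# ---------------------------------------------------------------------------
# Reading

def _parse_root(el: etree._Element, order: int, parent: Root | None,
                unit_factor: float, warn_missing_diam: list) -> list[Root]:
    poly = el.find("./geometry/polyline")
    if poly is None or len(poly) == 0:
        rid = el.get("ID", el.get("id", "?"))
        raise ValueError(f"root element ID={rid} has no polyline geometry")
    xs = [float(p.get("x")) * unit_factor for p in poly]
    ys = [float(p.get("y")) * unit_factor for p in poly]

    diam_fn = None
    for fn in el.findall("./functions/function"):
        if fn.get("name") == "diameter":
            diam_fn = fn
            break
    if diam_fn is not None and len(diam_fn) > 0:
        diams = [float(s.get("value")) * unit_factor for s in diam_fn]
        if len(diams) == 1:
            diams = diams * len(xs)
        elif len(diams) != len(xs):
            # resample per-node by index interpolation
            diams = list(np.interp(np.linspace(0, 1, len(xs)),
                                   np.linspace(0, 1, len(diams)), diams))
    else:
        warn_missing_diam.append(el.get("ID", "?"))
        diams = [DEFAULT_DIAMETER_MM] * len(xs)

    root = Root(xs[0], ys[0], diams[0], order=order, parent=parent)
    root.set_polyline(xs, ys, diams)

    ins = el.find("./properties/insertion_position")
    if ins is not None and ins.get("value") is not None:
        root.insertion_position_mm = float(ins.get("value")) * unit_factor
    elif parent is not None:
        root.insertion_position_mm = _project_abscissa(parent, xs[0], ys[0])

    out = [root]
    for child_el in el.findall("./root"):
        children = _parse_root(child_el, order + 1, root, unit_factor,
                               warn_missing_diam)
        root.children.append(children[0])
        out.extend(children)
    return out


def _project_abscissa(parent: Root, x: float, y: float) -> float:
    """Curvilinear abscissa on the parent polyline closest to (x, y)."""
    s = parent.abscissas()
    best_a, best_d = 0.0, math.inf
    for i in range(len(s) - 1):
        ax, ay = parent.xs[i], parent.ys[i]
        bx, by = parent.xs[i + 1], parent.ys[i + 1]
        vx, vy = bx - ax, by - ay
        L2 = vx * vx + vy * vy
        t = 0.0 if L2 == 0 else min(max(((x - ax) * vx + (y - ay) * vy) / L2, 0.0), 1.0)
        px, py = ax + t * vx, ay + t * vy
        d = math.hypot(x - px, y - py)
        if d < best_d:
            best_d, best_a = d, float(s[i] + t * math.sqrt(L2))
    return best_a


def read_rsml(source: str | Path, multiple_plants: str = "error") -> RootSystem:
    """Parse an RSML file back into a :class:`RootSystem`.

    The metadata ``unit`` is honored (mm assumed, with a warning, when
    absent).  ``multiple_plants`` controls files with several plants:
    ``"error"`` rejects them, ``"first"`` keeps the first plant only.
    """
    tree = etree.parse(str(source))
    rsml = tree.getroot()

    unit_el = rsml.find("./metadata/unit")
    if unit_el is None or not (unit_el.text or "").strip():
        warnings.warn(f"{source}: no unit in RSML metadata, assuming mm")
        unit_factor = 1.0
    else:
        unit = unit_el.text.strip().lower()
        if unit not in _UNIT_TO_MM:
            raise ValueError(f"{source}: unsupported RSML unit {unit!r}")
        unit_factor = _UNIT_TO_MM[unit]

    plants = rsml.findall("./scene/plant")
    if not plants:
        raise ValueError(f"{source}: RSML file contains no plant")
    if len(plants) > 1:
        if multiple_plants == "first":
            warnings.warn(f"{source}: {len(plants)} plants; keeping the first")
        else:
            raise ValueError(
                f"{source}: RSML file contains {len(plants)} plants; "
                "pass multiple_plants='first' to keep the first one"
            )
    plant = plants[0]

    warn_missing: list = []
    roots: list[Root] = []
    for axis_el in plant.findall("./root"):
        roots.extend(_parse_root(axis_el, 1, None, unit_factor, warn_missing))
    if warn_missing:
        warnings.warn(
            f"{source}: no diameter function for root(s) {warn_missing}; "
            f"defaulting to {DEFAULT_DIAMETER_MM} mm"
        )

    plant_type = plant.get("label") or "unknown"
    if plant_type not in ("fibrous", "tap"):
        plant_type = "unknown"
    system = RootSystem(roots=roots, plant_type=plant_type, params=None)
    system.validate()
    return system


# ---------------------------------------------------------------------------
# Ground truth

def _weighted_diameter(root: Root) -> float:
    """Length-weighted mean diameter along the polyline (trapezoidal)."""
    if root.n_nodes < 2:
        return float(root.diams[0])
    xs, ys, ds = map(np.asarray, (root.xs, root.ys, root.diams))
    seg = np.hypot(np.diff(xs), np.diff(ys))
    if seg.sum() == 0:
        return float(ds.mean())
    mids = 0.5 * (ds[:-1] + ds[1:])
    return float((mids * seg).sum() / seg.sum())


def _insertion_angle_deg(root: Root) -> float:
    """Unsigned angle between a lateral's initial direction and the parent
    tangent at the insertion abscissa, in [0, 180)."""
    if root.parent is None or root.n_nodes < 2:
        return math.nan
    vx = root.xs[1] - root.xs[0]
    vy = root.ys[1] - root.ys[0]
    n = math.hypot(vx, vy)
    if n == 0:
        return math.nan
    tx, ty = root.parent.tangent_at(root.insertion_position_mm)
    cosang = max(-1.0, min(1.0, (vx * tx + vy * ty) / n))
    ang = math.degrees(math.acos(cosang))
    return ang if ang < 180.0 else 0.0


def compute_ground_truth(system: RootSystem) -> GroundTruthRecord:
    """Measure the thirteen ground-truth traits of a root system.

    Lengths are polyline arc lengths; per-root diameters are length-weighted
    node means; lateral density is, for each axis, its lateral count divided
    by its own length, averaged over axes; width and depth are the extents
    of the node cloud.
    """
    axes = system.axes
    laterals = system.laterals
    if not axes:
        raise ValueError("root system has no axis")

    axis_lengths = np.array([r.length() for r in axes])
    lat_lengths = np.array([r.length() for r in laterals])
    tot_1 = float(axis_lengths.sum())
    tot_2 = float(lat_lengths.sum())

    densities = []
    for axis in axes:
        n_lat = len(axis.children)
        if n_lat == 0:
            densities.append(0.0)
        elif axis.length() > 0:
            densities.append(n_lat / axis.length())
    density = float(np.mean(densities)) if densities else math.nan

    if laterals:
        angles = [_insertion_angle_deg(r) for r in laterals]
        angles = [a for a in angles if not math.isnan(a)]
        mean_angle = float(np.mean(angles)) if angles else math.nan
        mean_lat_len = float(lat_lengths.mean())
        mean_lat_diam = float(np.mean([_weighted_diameter(r) for r in laterals]))
    else:
        mean_angle = mean_lat_len = mean_lat_diam = math.nan

    all_x = np.concatenate([np.asarray(r.xs) for r in system.roots])
    all_y = np.concatenate([np.asarray(r.ys) for r in system.roots])

    return GroundTruthRecord(
        tot_root_length=tot_1 + tot_2,
        tot_1_order_length=tot_1,
        tot_2plus_order_length=tot_2,
        mean_1_order_length=float(axis_lengths.mean()),
        mean_2plus_order_length=mean_lat_len,
        n_1_orders=len(axes),
        n_2plus_orders=len(laterals),
        mean_2plus_order_density=density,
        mean_1_order_diam=float(np.mean([_weighted_diameter(r) for r in axes])),
        mean_2plus_order_diam=mean_lat_diam,
        mean_2plus_order_angle=mean_angle,
        width=float(all_x.max() - all_x.min()),
        depth=float(all_y.max()),
        plant_type=system.plant_type,
    )


def ground_truth_table(systems, system_ids=None) -> pd.DataFrame:
    """Ground-truth records for many systems as one DataFrame.

    ``systems`` may be RootSystem objects or (RootSystem, params) tuples as
    returned by :func:`rootbench.simulator.generate_library`.
    """
    rows = []
    for i, item in enumerate(systems):
        system = item[0] if isinstance(item, tuple) else item
        rec = compute_ground_truth(system).to_dict()
        rec["system_id"] = system_ids[i] if system_ids is not None else i
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["system_id"] + TRAIT_COLUMNS + ["plant_type"]]
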