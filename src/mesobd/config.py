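"""Simulation-setup documents: schema, validation, round-tripping.

One YAML document describes a complete run: box and boundary modes,
timestep, thermal energy, colour-pair table, particle templates (the
hierarchy protein -> gestalt -> {geom, vdw[], charges[], hydro,
restraints[]} plus bonds), fixed walls, species placement, constant
density interfaces, and output settings.  Unknown keys are rejected with
the path to the offending entry, and a loaded configuration dumps back to
an equivalent document (load -> dump -> load is stable).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .boundaries import ConfigurationError, DensityInterface, SimulationBox
from .model import (Bond, ColourPair, ColourTable, ConstantForce, GeomSpec,
                    GestaltTemplate, HarmonicRestraint, HydroSphere,
                    PointCharge, ProteinTemplate, SystemBuilder, VdWSphere,
                    WallTemplate)

SCHEMA_VERSION = 1

__all__ = ["SCHEMA_VERSION", "SimulationConfig", "load_config", "dump_config"]


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}")


@dataclass
class SimulationConfig:
    box: SimulationBox
    timestep_ps: float
    steps: int
    kT: float = 2.4361e-3
    output_stride: int = 100
    hi: bool = False
    tensor_stride: int = 1
    seed: int = 0
    kappa_per_nm: float = 0.0
    eps_r: float = 80.0
    colours: ColourTable = field(default_factory=ColourTable)
    templates: dict[str, ProteinTemplate] = field(default_factory=dict)
    walls: list[WallTemplate] = field(default_factory=list)
    species: list[dict] = field(default_factory=list)
    interfaces: list[DensityInterface] = field(default_factory=list)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dump_config(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def build_system(self, rng=None):
        """Instantiate all species and compile the system.

        ``count`` copies of each species are placed on a jittered grid (or
        at explicit ``positions``); interface-managed species additionally
        reserve ``capacity`` dormant slots.  Returns (system, state is the
        caller's job via ``system.initial_state``).
        """
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        builder = SystemBuilder(self.box, self.colours, kT=self.kT,
                                kappa=self.kappa_per_nm, eps_r=self.eps_r)
        for w in self.walls:
            builder.add_wall(w)
        L = self.box.lengths_array
        for sp in self.species:
            tpl = self.templates.get(sp["template"])
            if tpl is None:
                raise ConfigurationError(
                    f"species refers to unknown template {sp['template']!r}")
            positions = sp.get("positions")
            count = sp.get("count", 0 if positions else 1)
            if positions is not None:
                for p in positions:
                    builder.instantiate(tpl, position=p)
            else:
                for _ in range(count):
                    for _attempt in range(200):
                        p = rng.uniform(0.0, 1.0, 3) * L
                        try:
                            builder.instantiate(tpl, position=p)
                            break
                        except Exception:
                            continue
                    else:
                        raise ConfigurationError(
                            f"could not place species {sp['template']!r}")
            if sp.get("capacity", 0):
                builder.reserve(tpl, int(sp["capacity"]))
        return builder.compile()


# ---------------------------------------------------------------------------
# parsing


def _parse_gestalt(d: dict, where: str) -> GestaltTemplate:
    _check_keys(d, {"geom", "position", "vdw", "charges", "hydro",
                    "restraints"}, where)
    g = d["geom"]
    _check_keys(g, {"d_tr", "d_rot", "mass"}, f"{where}.geom")
    geom = GeomSpec(d_tr=float(g["d_tr"]), d_rot=float(g.get("d_rot", 0.0)),
                    mass=None if g.get("mass") is None else float(g["mass"]))
    vdw = []
    for i, s in enumerate(d.get("vdw", [])):
        _check_keys(s, {"offset", "radius", "colour"}, f"{where}.vdw[{i}]")
        vdw.append(VdWSphere(tuple(s.get("offset", (0, 0, 0))),
                             float(s["radius"]), int(s["colour"])))
    charges = []
    for i, c in enumerate(d.get("charges", [])):
        _check_keys(c, {"offset", "q", "burial"}, f"{where}.charges[{i}]")
        charges.append(PointCharge(tuple(c.get("offset", (0, 0, 0))),
                                   float(c["q"]), float(c.get("burial", 0.0))))
    hydro = None
    if d.get("hydro") is not None:
        h = d["hydro"]
        _check_keys(h, {"radius", "d_self"}, f"{where}.hydro")
        hydro = HydroSphere(float(h["radius"]), float(h["d_self"]))
    restraints = []
    for i, r in enumerate(d.get("restraints", [])):
        kind = r.get("type")
        if kind == "harmonic":
            _check_keys(r, {"type", "k", "center"}, f"{where}.restraints[{i}]")
            restraints.append(HarmonicRestraint(float(r["k"]),
                                                tuple(r.get("center", (0, 0, 0)))))
        elif kind == "constant":
            _check_keys(r, {"type", "f"}, f"{where}.restraints[{i}]")
            restraints.append(ConstantForce(tuple(r["f"])))
        else:
            raise ConfigurationError(
                f"unknown restraint type {kind!r} in {where}.restraints[{i}]")
    return GestaltTemplate(geom=geom, position=tuple(d.get("position", (0, 0, 0))),
                           vdw=tuple(vdw), charges=tuple(charges),
                           hydro=hydro, restraints=tuple(restraints))


def _parse_template(d: dict) -> ProteinTemplate:
    name = d.get("name", "unnamed")
    where = f"templates[{name}]"
    _check_keys(d, {"name", "gestalten", "bonds"}, where)
    gestalten = tuple(_parse_gestalt(g, f"{where}.gestalten[{i}]")
                      for i, g in enumerate(d.get("gestalten", [])))
    bonds = []
    for i, b in enumerate(d.get("bonds", [])):
        _check_keys(b, {"a", "b", "k2", "k4", "length", "hook_a", "hook_b"},
                    f"{where}.bonds[{i}]")
        bonds.append(Bond(a=int(b["a"]), b=int(b["b"]), k2=float(b.get("k2", 0.0)),
                          k4=float(b.get("k4", 0.0)), length=float(b["length"]),
                          hook_a=tuple(b.get("hook_a", (0, 0, 0))),
                          hook_b=tuple(b.get("hook_b", (0, 0, 0)))))
    return ProteinTemplate(name, gestalten, tuple(bonds))


TOP_KEYS = {"schema", "box", "timestep_ps", "steps", "kT", "output_stride",
            "hi", "tensor_stride", "seed", "kappa_per_nm", "eps_r",
            "colour_pairs", "templates", "walls", "species", "interfaces"}


def parse_config(doc: dict) -> SimulationConfig:
    if not isinstance(doc, dict):
        raise ConfigurationError("setup document must be a mapping")
    _check_keys(doc, TOP_KEYS, "top level")
    schema = doc.get("schema", SCHEMA_VERSION)
    if schema > SCHEMA_VERSION:
        raise ConfigurationError(
            f"document schema {schema} is newer than supported {SCHEMA_VERSION}")

    b = doc["box"]
    _check_keys(b, {"lengths", "modes"}, "box")
    box = SimulationBox(tuple(float(x) for x in b["lengths"]),
                        tuple(b.get("modes", ("periodic",) * 3)))

    colours = ColourTable()
    for i, cp in enumerate(doc.get("colour_pairs", [])):
        _check_keys(cp, {"colours", "epsilon", "sigma", "attractive",
                         "cutoff", "r_lin"}, f"colour_pairs[{i}]")
        a, b_ = cp["colours"]
        colours.set(int(a), int(b_), ColourPair(
            epsilon=float(cp["epsilon"]), sigma=float(cp["sigma"]),
            attractive=bool(cp.get("attractive", False)),
            cutoff=None if cp.get("cutoff") is None else float(cp["cutoff"]),
            r_lin=None if cp.get("r_lin") is None else float(cp["r_lin"])))

    templates = {}
    for t in doc.get("templates", []):
        tpl = _parse_template(t)
        templates[tpl.name] = tpl

    walls = []
    for i, w in enumerate(doc.get("walls", [])):
        _check_keys(w, {"name", "spheres", "charges"}, f"walls[{i}]")
        spheres = tuple(VdWSphere(tuple(s["offset"]), float(s["radius"]),
                                  int(s["colour"]))
                        for s in w.get("spheres", []))
        charges = tuple(PointCharge(tuple(c["offset"]), float(c["q"]),
                                    float(c.get("burial", 0.0)))
                        for c in w.get("charges", []))
        walls.append(WallTemplate(w.get("name", f"wall{i}"), spheres, charges))

    species = []
    for i, sp in enumerate(doc.get("species", [])):
        _check_keys(sp, {"template", "count", "capacity", "positions"},
                    f"species[{i}]")
        species.append(dict(sp))

    interfaces = []
    for i, it in enumerate(doc.get("interfaces", [])):
        _check_keys(it, {"axis", "side", "species", "rho"}, f"interfaces[{i}]")
        interfaces.append(DensityInterface(axis=it["axis"], side=it["side"],
                                           species=it["species"],
                                           rho=float(it["rho"])))

    cfg = SimulationConfig(
        box=box, timestep_ps=float(doc["timestep_ps"]), steps=int(doc["steps"]),
        kT=float(doc.get("kT", 2.4361e-3)),
        output_stride=int(doc.get("output_stride", 100)),
        hi=bool(doc.get("hi", False)),
        tensor_stride=int(doc.get("tensor_stride", 1)),
        seed=int(doc.get("seed", 0)),
        kappa_per_nm=float(doc.get("kappa_per_nm", 0.0)),
        eps_r=float(doc.get("eps_r", 80.0)),
        colours=colours, templates=templates, walls=walls, species=species,
        interfaces=interfaces)

    for sp in species:
        if sp["template"] not in templates:
            raise ConfigurationError(
                f"species refers to unknown template {sp['template']!r}")
    for it in interfaces:
        if it.species not in templates:
            raise ConfigurationError(
                f"interface refers to unknown template {it.species!r}")
    return cfg


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


# ---------------------------------------------------------------------------
# dumping


def _dump_gestalt(g: GestaltTemplate) -> dict:
    d = {"geom": {"d_tr": g.geom.d_tr, "d_rot": g.geom.d_rot,
                  "mass": g.geom.mass},
         "position": list(g.position)}
    if g.vdw:
        d["vdw"] = [{"offset": list(s.offset), "radius": s.radius,
                     "colour": s.colour} for s in g.vdw]
    if g.charges:
        d["charges"] = [{"offset": list(c.offset), "q": c.q,
                         "burial": c.burial} for c in g.charges]
    if g.hydro is not None:
        d["hydro"] = {"radius": g.hydro.radius, "d_self": g.hydro.d_self}
    if g.restraints:
        rs = []
        for r in g.restraints:
            if isinstance(r, HarmonicRestraint):
                rs.append({"type": "harmonic", "k": r.k,
                           "center": list(r.center)})
            else:
                rs.append({"type": "constant", "f": list(r.f)})
        d["restraints"] = rs
    return d


def dump_config(cfg: SimulationConfig) -> dict:
    doc = {
        "schema": SCHEMA_VERSION,
        "box": {"lengths": list(cfg.box.lengths), "modes": list(cfg.box.modes)},
        "timestep_ps": cfg.timestep_ps,
        "steps": cfg.steps,
        "kT": cfg.kT,
        "output_stride": cfg.output_stride,
        "hi": cfg.hi,
        "tensor_stride": cfg.tensor_stride,
        "seed": cfg.seed,
        "kappa_per_nm": cfg.kappa_per_nm,
        "eps_r": cfg.eps_r,
        "colour_pairs": [
            {"colours": list(pair), "epsilon": p.epsilon, "sigma": p.sigma,
             "attractive": p.attractive, "cutoff": p.cutoff, "r_lin": p.r_lin}
            for pair, p in cfg.colours.items()],
        "templates": [
            {"name": t.name,
             "gestalten": [_dump_gestalt(g) for g in t.gestalten],
             "bonds": [{"a": b.a, "b": b.b, "k2": b.k2, "k4": b.k4,
                        "length": b.length, "hook_a": list(b.hook_a),
                        "hook_b": list(b.hook_b)} for b in t.bonds]}
            for t in cfg.templates.values()],
        "walls": [
            {"name": w.name,
             "spheres": [{"offset": list(s.offset), "radius": s.radius,
                          "colour": s.colour} for s in w.spheres],
             "charges": [{"offset": list(c.offset), "q": c.q,
                          "burial": c.burial} for c in w.charges]}
            for w in cfg.walls],
        "species": cfg.species,
        "interfaces": [
            {"axis": ["x", "y", "z"][it.axis], "side": it.side,
             "species": it.species, "rho": it.rho}
            for it in cfg.interfaces],
    }
    return doc


def save_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dump_config(cfg), sort_keys=False))
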