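"""Run configuration, the main simulation loop, presets, and parameter scans.

One solver step advances the perimeter chemistry by ``dt``; a *frame* is
``steps_per_frame`` solver steps, after which the boundary is moved once
and the state recorded.  The per-frame loop is:

    evaluate stimulus -> signal -> chemistry substeps -> normal velocity
    -> extend speed to grid -> advance level set -> extract new perimeter
    -> conservative field transfer (geometric dilution) -> record

All randomness flows through a single seeded generator, so a given config
and seed reproduce a run bit for bit.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
import math
import tomllib
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from . import boundary as bd
from . import rd_core as rd
from . import stimulus as st

logger = logging.getLogger("chemopod")

SCHEMA_VERSION = 1

#: the cell diameter in model length units; "across the cell" in gradient
#: protocols means across this span
CELL_DIAMETER = 10.0


@dataclasses.dataclass
class SimulationConfig:
    """Complete, serialisable description of one simulation run."""

    model: rd.ModelParameters = dataclasses.field(default_factory=rd.ModelParameters)
    mechanics: bd.MechanicsParameters = dataclasses.field(default_factory=bd.MechanicsParameters)
    stimulus: st.StimulusSpec = dataclasses.field(default_factory=st.StimulusSpec)
    n_nodes: int = 200
    frames: int = 5000
    steps_per_frame: int = 10
    seed: int = 0
    grid_shape: int = 128
    grid_spacing: float = CELL_DIAMETER / 32.0
    initial_radius: float = 0.5 * CELL_DIAMETER
    heading_window: int = 20
    label: str = "run"

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "SimulationConfig":
        d = dict(d)
        d.pop("schema_version", None)
        model = dict(d.pop("model", {}))
        sig = st.SignalParameters(**model.pop("signal", {}))
        mech = bd.MechanicsParameters(**d.pop("mechanics", {}))
        stim = d.pop("stimulus", {})
        for key in ("gradient_vector", "reference_point", "source_position"):
            if key in stim:
                stim[key] = tuple(stim[key])
        return cls(model=rd.ModelParameters(signal=sig, **model),
                   mechanics=mech, stimulus=st.StimulusSpec(**stim), **d)

    def to_toml(self) -> str:
        return _emit_toml(self.to_dict())

    @classmethod
    def from_toml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(tomllib.loads(text))


def _emit_toml(d: Dict, prefix: str = "") -> str:
    """Minimal TOML emitter for the nested-dict config schema."""
    out = io.StringIO()
    tables = []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        else:
            out.write(f"{k} = {_toml_value(v)}\n")
    for k, v in tables:
        name = f"{prefix}{k}"
        out.write(f"\n[{name}]\n")
        out.write(_emit_toml(v, prefix=name + "."))
    return out.getvalue()


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(float(v))
    if isinstance(v, int):
        return str(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


@dataclasses.dataclass
class SimulationOutput:
    """Recorded frames of one run plus run metadata.

    Arrays have leading dimension ``frames + 1`` (frame 0 is the initial
    state), except when the run aborted early, in which case ``aborted``
    holds the reason and the arrays cover the completed frames.
    """

    config: SimulationConfig
    times: np.ndarray
    nodes: np.ndarray        # (F, N, 2)
    a: np.ndarray            # (F, N)
    c: np.ndarray            # (F, N)
    b: np.ndarray            # (F,)
    centroid: np.ndarray     # (F, 2)
    area: np.ndarray         # (F,)
    heading: np.ndarray      # (F,) degrees; NaN while undefined
    gradient_direction: np.ndarray = None  # (F,) degrees; NaN without a gradient
    aborted: Optional[str] = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def mesh(self, frame: int) -> bd.PerimeterMesh:
        return bd.PerimeterMesh(self.nodes[frame])

    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "time": self.times,
            "x": self.centroid[:, 0],
            "y": self.centroid[:, 1],
            "area": self.area,
            "heading": self.heading,
        })

    # -- persistence ---------------------------------------------------------
    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with h5py.File(out_dir / "snapshots.h5", "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["config"] = json.dumps(self.config.to_dict())
            f.attrs["aborted"] = self.aborted or ""
            for name in ("times", "nodes", "a", "c", "b", "centroid", "area",
                         "heading", "gradient_direction"):
                f.create_dataset(name, data=getattr(self, name))
        self.trajectory().to_csv(out_dir / "trajectory.csv", index=False)
        (out_dir / "config.toml").write_text(self.config.to_toml())
        return out_dir

    @classmethod
    def load(cls, out_dir) -> "SimulationOutput":
        out_dir = Path(out_dir)
        with h5py.File(out_dir / "snapshots.h5", "r") as f:
            cfg = SimulationConfig.from_dict(json.loads(f.attrs["config"]))
            kw = {name: f[name][...] for name in
                  ("times", "nodes", "a", "c", "b", "centroid", "area",
                   "heading", "gradient_direction")}
            aborted = f.attrs["aborted"] or None
        return cls(config=cfg, aborted=aborted, **kw)


def _heading(centroids: List[np.ndarray], window: int) -> float:
    if len(centroids) < 2:
        return float("nan")
    lo = max(0, len(centroids) - 1 - window)
    d = centroids[-1] - centroids[lo]
    if np.hypot(*d) < 1e-9:
        return float("nan")
    return math.degrees(math.atan2(d[1], d[0]))


def run_simulation(config: SimulationConfig, progress: bool = False) -> SimulationOutput:
    """Execute the full moving-boundary simulation for ``config``.

    Identical seed and config give identical output.  Geometric failure
    (collapse, self-intersection, failed transfer) aborts the run and
    returns the partial output with the reason in ``aborted``.
    """
    cfg = config
    model = cfg.model
    rng = np.random.default_rng(cfg.seed)
    mesh = bd.PerimeterMesh.circle(cfg.initial_radius, (0.0, 0.0), cfg.n_nodes)
    a0, b0, c0 = rd.uniform_steady_state(model, model.signal.autocatalysis_coupling)
    fields = rd.SurfaceFields(np.full(cfg.n_nodes, a0), np.full(cfg.n_nodes, c0), b0)
    spec = cfg.stimulus
    dt_frame = model.dt * cfg.steps_per_frame
    Kd = model.signal.occupancy_Kd

    times = [0.0]
    rec_nodes = [mesh.nodes.copy()]
    rec_a = [fields.a.copy()]
    rec_c = [fields.c.copy()]
    rec_b = [fields.b]
    area, centroid = bd.polygon_area_centroid(mesh)
    rec_centroid = [centroid]
    rec_area = [area]
    rec_heading = [float("nan")]

    def _grad_dir(sp: st.StimulusSpec, t_now: float) -> float:
        if sp.kind in ("linear", "scheduled") and sp.gradient_magnitude > 0 and t_now >= sp.onset_time:
            return sp.gradient_direction
        return float("nan")

    rec_grad = [_grad_dir(spec, 0.0)]
    aborted = None
    t = 0.0

    for frame in range(1, cfg.frames + 1):
        try:
            ops = rd.Operators(mesh, model)
            for _ in range(cfg.steps_per_frame):
                Y = st.occupancy_at(mesh.nodes, t, spec, Kd)
                s = st.signal_field(np.broadcast_to(Y, (mesh.n_nodes,)), fields.a,
                                    model.signal, rng)
                fields = rd.step_fields(fields, mesh, s, model, operators=ops)
                t += model.dt
            grid = bd.grid_for_mesh(mesh, (cfg.grid_shape, cfg.grid_shape), cfg.grid_spacing)
            protrusion = bd.extend_velocity(
                mesh, np.minimum(cfg.mechanics.protrusion_coefficient * fields.a,
                                 cfg.mechanics.max_protrusion_speed), grid)
            grid = bd.move_boundary(grid, protrusion, cfg.mechanics, dt_frame)
            new_mesh = bd.extract_perimeter(grid, cfg.n_nodes)
            # keep the arc-length origin continuous across frames: node 0 of
            # the new mesh is the node closest to node 0 of the old one
            shift = int(np.argmin(((new_mesh.nodes - mesh.nodes[0]) ** 2).sum(axis=1)))
            if shift:
                new_mesh = bd.PerimeterMesh(np.roll(new_mesh.nodes, -shift, axis=0))
            if not new_mesh.is_simple():
                raise bd.MeshError("perimeter self-intersection")
            fields = rd.transfer_fields(mesh, new_mesh, fields)
            mesh = new_mesh
            area, centroid = bd.polygon_area_centroid(mesh)
        except (bd.CollapseError, bd.GeometryError, bd.MeshError,
                rd.TransferError, rd.NumericalError) as exc:
            aborted = f"frame {frame}: {exc}"
            logger.error("run aborted at %s", aborted)
            break
        times.append(t)
        rec_nodes.append(mesh.nodes.copy())
        rec_a.append(fields.a.copy())
        rec_c.append(fields.c.copy())
        rec_b.append(fields.b)
        rec_centroid.append(centroid)
        rec_area.append(area)
        rec_heading.append(_heading(rec_centroid, cfg.heading_window))
        rec_grad.append(_grad_dir(spec, t))
        if (spec.kind == "scheduled" and spec.reorientation_interval > 0
                and frame % spec.reorientation_interval == 0):
            heading = rec_heading[-1]
            if not math.isnan(heading):
                spec = st.reorient_gradient(spec, heading, spec.reorientation_offset)
                logger.info("frame %d: gradient re-aimed to %.1f deg", frame,
                            spec.gradient_direction % 360.0)
        if progress and frame % 200 == 0:
            logger.info("frame %d/%d area %.1f", frame, cfg.frames, area)

    return SimulationOutput(
        config=cfg,
        times=np.array(times),
        nodes=np.array(rec_nodes),
        a=np.array(rec_a),
        c=np.array(rec_c),
        b=np.array(rec_b),
        centroid=np.array(rec_centroid),
        area=np.array(rec_area),
        heading=np.array(rec_heading),
        gradient_direction=np.array(rec_grad),
        aborted=aborted,
    )


def aggregate_activator_timeseries(output: SimulationOutput) -> np.ndarray:
    """Per-frame line integral of the activator over the perimeter."""
    out = np.empty(output.n_frames)
    for i in range(output.n_frames):
        w = output.mesh(i).node_weights()
        out[i] = float(np.dot(w, output.a[i]))
    return out


# ---------------------------------------------------------------------------
# Presets: the protocols behind each in-silico experiment
# ---------------------------------------------------------------------------

PRESET_NAMES = ("random_migration", "gradient_panel", "steep_gradient", "cringe", "circling")

#: far-edge concentrations (nM) of the moderate-gradient panel; near edge 5.3
GRADIENT_PANEL_NM = (5.5, 5.7, 6.1, 6.6)
GRADIENT_PANEL_NEAR_NM = 5.3


def _linear_spec(near: float, far: float, direction_deg: float = 0.0,
                 onset: float = 0.0, **kw) -> st.StimulusSpec:
    """Linear gradient reading ``near`` at the cell rear and ``far`` at the
    front across one cell diameter, centred on the initial centroid."""
    mag = (far - near) / CELL_DIAMETER
    th = math.radians(direction_deg)
    return st.StimulusSpec(
        kind=kw.pop("kind", "linear"),
        reference_concentration=0.5 * (near + far),
        gradient_vector=(mag * math.cos(th), mag * math.sin(th)),
        reference_point=(0.0, 0.0),
        onset_time=onset,
        **kw,
    )


def preset(name: str, overrides: Optional[Dict] = None, seed: int = 0):
    """Documented configuration(s) for a named protocol.

    ``gradient_panel`` returns a list of four configs (far-edge 5.5, 5.7,
    6.1 and 6.6 nM, near edge 5.3 nM); every other preset returns a single
    config.  ``overrides`` is a flat dict of SimulationConfig field
    overrides applied after the preset defaults.
    """
    if name not in PRESET_NAMES:
        raise st.ConfigurationError(
            f"unknown preset {name!r}; valid presets: {PRESET_NAMES}")

    def make(stim: st.StimulusSpec, label: str) -> SimulationConfig:
        cfg = SimulationConfig(stimulus=stim, seed=seed, label=label)
        for k, v in (overrides or {}).items():
            if not hasattr(cfg, k):
                raise st.ConfigurationError(f"unknown config field {k!r}")
            setattr(cfg, k, v)
        return cfg

    if name == "random_migration":
        return make(st.StimulusSpec(kind="none"), name)
    if name == "gradient_panel":
        return [make(_linear_spec(GRADIENT_PANEL_NEAR_NM, far), f"gradient_{far}nM")
                for far in GRADIENT_PANEL_NM]
    if name == "steep_gradient":
        # occupancy 0 -> 20% across the cell: rear edge 0 nM, front Kd/4
        Kd = rd.ModelParameters().signal.occupancy_Kd
        far = Kd * 0.2 / 0.8
        mag = far / CELL_DIAMETER
        stim = st.StimulusSpec(kind="linear", reference_concentration=far / 2.0,
                               gradient_vector=(mag, 0.0), reference_point=(0.0, 0.0))
        return make(stim, name)
    if name == "cringe":
        # sudden uniform jump to (near-)full receptor occupancy + adaptation
        stim = st.StimulusSpec(kind="uniform_step", reference_concentration=1e5,
                               onset_time=1000.0, adaptation_timescale=400.0)
        return make(stim, name)
    if name == "circling":
        stim = _linear_spec(5.3, 7.0, kind="scheduled",
                            reorientation_interval=200, reorientation_offset=90.0)
        return make(stim, name)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

SCAN_PARAMETERS = ("D_a", "D_c", "r_a", "r_b", "b_c", "r_c")


def classify_run(output: SimulationOutput,
                 displacement_threshold: float = 0.5 * CELL_DIAMETER,
                 repetition_threshold: float = 0.9) -> str:
    """Heuristic run outcome: ``migrates``, ``repetitious``, ``stalled`` or
    ``aborted``.

    A run is repetitious when the perimeter activator pattern returns
    almost exactly to an earlier configuration (lagged pattern correlation
    above ``repetition_threshold``) while the cell fails to displace; it is
    stalled when it merely fails to displace half a diameter.
    """
    if output.aborted:
        return "aborted"
    disp = float(np.linalg.norm(output.centroid[-1] - output.centroid[0]))
    if disp >= displacement_threshold:
        return "migrates"
    # lagged correlation of the activator pattern, skipping the transient
    f0 = output.n_frames // 4
    A = output.a[f0:]
    if len(A) > 20:
        best = -1.0
        for lag in range(5, len(A) // 2):
            x = A[:-lag].ravel()
            y = A[lag:].ravel()
            if x.std() > 0 and y.std() > 0:
                best = max(best, float(np.corrcoef(x, y)[0, 1]))
        if best > repetition_threshold:
            return "repetitious"
    return "stalled"


def robustness_scan(base: SimulationConfig, factors: Sequence[float] = (0.5, 2.0),
                    parameters: Sequence[str] = SCAN_PARAMETERS,
                    n_replicates: int = 1, include_control: bool = False) -> pd.DataFrame:
    """Re-run the base protocol with each model parameter halved / doubled.

    Returns one row per (parameter, factor, replicate) with the outcome
    classification from :func:`classify_run`.  Individual aborts are
    recorded and the scan continues.
    """
    rows = []
    jobs = [("control", 1.0)] if include_control else []
    jobs += [(p, f) for p in parameters for f in factors]
    for pname, factor in jobs:
        for rep in range(n_replicates):
            cfg = dataclasses.replace(base, seed=base.seed + rep,
                                      label=f"{pname}_x{factor}_r{rep}")
            if pname != "control":
                model = dataclasses.replace(base.model)
                setattr(model, pname, getattr(base.model, pname) * factor)
                cfg = dataclasses.replace(cfg, model=model)
            out = run_simulation(cfg)
            rows.append({
                "parameter": pname, "factor": factor, "replicate": rep,
                "outcome": classify_run(out),
                "displacement": float(np.linalg.norm(out.centroid[-1] - out.centroid[0])),
            })
    return pd.DataFrame(rows)


def noise_scan(gradients_nM: Sequence[float], noise_amplitudes: Sequence[float],
               base: Optional[SimulationConfig] = None, n_seeds: int = 3) -> pd.DataFrame:
    """Mean chemotaxis index on a (gradient, noise) grid.

    ``gradients_nM`` are far-edge concentrations with the near edge at
    5.3 nM (0 means no stimulus); each cell of the matrix averages the
    chemotaxis index over ``n_seeds`` seeds.
    """
    from .analysis import chemotaxis_index
    if len(gradients_nM) < 2 or len(noise_amplitudes) < 2:
        raise ValueError("need at least 2 levels on each scan axis")
    if base is None:
        base = SimulationConfig()
    rows = []
    for g in gradients_nM:
        for eta in noise_amplitudes:
            cis = []
            for k in range(n_seeds):
                stim = (st.StimulusSpec(kind="none") if g <= GRADIENT_PANEL_NEAR_NM
                        else _linear_spec(GRADIENT_PANEL_NEAR_NM, g))
                sig = dataclasses.replace(base.model.signal,
                                          autocatalysis_noise_amplitude=eta,
                                          receptor_noise_amplitude=eta)
                model = dataclasses.replace(base.model, signal=sig)
                cfg = dataclasses.replace(base, model=model, stimulus=stim,
                                          seed=base.seed + k, label=f"g{g}_n{eta}_s{k}")
                out = run_simulation(cfg)
                cis.append(chemotaxis_index(out.centroid, stim.gradient_direction
                                            if g > GRADIENT_PANEL_NEAR_NM else 0.0))
            rows.append({"gradient_nM": g, "noise": eta,
                         "chemotaxis_index": float(np.mean(cis)), "n": len(cis)})
    return pd.DataFrame(rows)
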