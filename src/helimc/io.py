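"""Configuration, table persistence, and the end-to-end pipeline.

The canonical on-disk dialect is TSV with ``#``-prefixed metadata header
lines, JSON for reports and the run manifest, and XYZ for conformation
snapshots.  All writes go through a temp-file rename so a crash never
leaves a half-written table behind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .microcanonical import analyze_dos
from .prevalence import prevalence_field
from .reweight import mean_energy_and_specific_heat, wham, wham_2d
from .sampler import EnergyHistogram, JointHistogram, build_schedule, run_grid

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "persist_tables",
    "pipeline_run",
    "write_histogram_tsv",
    "read_histogram_tsv",
    "write_dos_tsv",
    "read_dos_tsv",
]

_SCHEDULE_KEYS = {
    "n", "sweeps", "burn_in", "exchange_interval", "move_mix", "local_step",
    "rot_max", "e_min", "e_max", "e_bin", "q_min", "q_max", "q_bin",
    "exchange_axes", "init", "t_min", "t_max", "n_temperatures",
    "s_tau_min", "s_tau_max", "n_s_tau",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with model defaults filled in."""

    schedule: dict = field(default_factory=dict)
    window: int = 51
    polyorder: int = 4
    prominence_threshold: float | None = None
    edge_trim: int = 2
    out_dir: str = "helimc_out"
    seed: int = 0
    log_level: str = "info"

    def __post_init__(self):
        unknown = set(self.schedule) - _SCHEDULE_KEYS
        if unknown:
            raise ValueError(
                f"unknown schedule key(s): {', '.join(sorted(unknown))}"
            )
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and > polyorder")
        if "s_tau_min" in self.schedule and self.schedule["s_tau_min"] <= 0:
            raise ValueError("s_tau_min must be positive")
        if "s_tau_max" in self.schedule and self.schedule["s_tau_max"] <= 0:
            raise ValueError("s_tau_max must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def build_schedule(self, **overrides):
        return build_schedule(dict(self.schedule), seed=self.seed, **overrides)


_CONFIG_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected by name, omitted keys
    fall back to the N=30 defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    _atomic_write(path, yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def _atomic_write(path, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_histogram_tsv(hist, path) -> None:
    lines = [
        f"# beta={float(hist.beta)!r}",
        f"# s_tau={float(hist.s_tau)!r}",
        f"# M={hist.total}",
        f"# bin_width={float(hist.edges[1] - hist.edges[0])!r}",
        f"# e_min={float(hist.edges[0])!r}",
        f"# underflow={hist.underflow}",
        f"# overflow={hist.overflow}",
        f"# n_bins={len(hist.counts) if hist.counts.ndim == 1 else hist.counts.shape[0]}",
    ]
    if isinstance(hist, JointHistogram):
        lines.append(f"# q_bin_width={float(hist.q_edges[1] - hist.q_edges[0])!r}")
        lines.append(f"# q_min={float(hist.q_edges[0])!r}")
        lines.append(f"# n_q_bins={hist.counts.shape[1]}")
        lines.append("E\tq\tcount")
        ei, qi = np.nonzero(hist.counts)
        for a, b in zip(ei, qi):
            lines.append(
                f"{hist.centers[a]:.6f}\t{hist.q_centers[b]:.6f}\t{hist.counts[a, b]}"
            )
    else:
        lines.append("E\tcount")
        for c, v in zip(hist.centers, hist.counts):
            if v:
                lines.append(f"{c:.6f}\t{v}")
    _atomic_write(path, "\n".join(lines) + "\n")


def _parse_meta(path):
    meta, rows, header = {}, [], None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "=" not in line:
                    raise ValueError(f"malformed header line in {path}: {line!r}")
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
            elif header is None:
                header = line.split("\t")
            elif line:
                rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"no table header in {path}")
    return meta, header, rows


def read_histogram_tsv(path):
    """Round-trip reader for :func:`write_histogram_tsv`; reconstructs the
    full (dense) count arrays bitwise for integer counts."""
    meta, header, rows = _parse_meta(path)
    try:
        beta = float(meta["beta"])
        s_tau = float(meta["s_tau"])
        bw = float(meta["bin_width"])
        e_min = float(meta["e_min"])
        m = int(meta["M"])
    except KeyError as exc:
        raise ValueError(f"missing header field {exc} in {path}") from exc
    under = int(meta.get("underflow", 0))
    over = int(meta.get("overflow", 0))
    if "q_bin_width" in meta:
        qw = float(meta["q_bin_width"])
        q_min = float(meta["q_min"])
        es = np.array([float(r[0]) for r in rows])
        qs = np.array([float(r[1]) for r in rows])
        cs = np.array([int(r[2]) for r in rows])
        n_e = int(meta["n_bins"]) if "n_bins" in meta else (
            int(round((es.max() - e_min) / bw)) + 1 if len(es) else 1)
        n_q = int(meta["n_q_bins"]) if "n_q_bins" in meta else (
            int(round((qs.max() - q_min) / qw)) + 1 if len(qs) else 1)
        counts = np.zeros((n_e, n_q), np.int64)
        ei = np.round((es - e_min - bw / 2) / bw).astype(int)
        qi = np.round((qs - q_min - qw / 2) / qw).astype(int)
        counts[ei, qi] = cs
        edges = e_min + bw * np.arange(n_e + 1)
        q_edges = q_min + qw * np.arange(n_q + 1)
        h = JointHistogram(beta, s_tau, edges, counts, under, over, q_edges)
    else:
        es = np.array([float(r[0]) for r in rows])
        cs = np.array([int(r[1]) for r in rows])
        n_e = int(meta["n_bins"]) if "n_bins" in meta else (
            int(round((es.max() - e_min) / bw)) + 1 if len(es) else 1)
        counts = np.zeros(n_e, np.int64)
        ei = np.round((es - e_min - bw / 2) / bw).astype(int)
        counts[ei] = cs
        edges = e_min + bw * np.arange(n_e + 1)
        h = EnergyHistogram(beta, s_tau, edges, counts, under, over)
    if h.total != m:
        raise ValueError(f"count total mismatch in {path}")
    return h


def write_dos_tsv(dos, path) -> None:
    lines = [
        f"# gauge_index={dos.gauge_index}",
        f"# converged={dos.converged}",
        f"# iterations={dos.iterations}",
    ]
    if dos.is_2d:
        lines.append("E\tq\tlog_g")
        for a in range(len(dos.energies)):
            for b in range(len(dos.q_values)):
                if np.isfinite(dos.log_g[a, b]):
                    lines.append(
                        f"{dos.energies[a]:.6f}\t{dos.q_values[b]:.6f}\t"
                        f"{dos.log_g[a, b]:.12e}"
                    )
    else:
        lines.append("E\tlog_g\tsupport")
        for e, lg, s in zip(dos.energies, dos.log_g, dos.support):
            lines.append(
                f"{e:.6f}\t{lg if np.isfinite(lg) else '-inf'}\t{int(s)}"
            )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_dos_tsv(path):
    from .reweight import DensityOfStates

    meta, header, rows = _parse_meta(path)
    gauge = int(meta["gauge_index"])
    conv = meta.get("converged", "True") == "True"
    iters = int(meta.get("iterations", 0))
    if header[:3] == ["E", "q", "log_g"]:
        es = sorted({float(r[0]) for r in rows})
        qs = sorted({float(r[1]) for r in rows})
        e_ix = {e: i for i, e in enumerate(es)}
        q_ix = {q: i for i, q in enumerate(qs)}
        log_g = np.full((len(es), len(qs)), -np.inf)
        for r in rows:
            log_g[e_ix[float(r[0])], q_ix[float(r[1])]] = float(r[2])
        return DensityOfStates(
            np.array(es), log_g, gauge, np.isfinite(log_g), np.array(qs),
            conv, iters,
        )
    es = np.array([float(r[0]) for r in rows])
    log_g = np.array(
        [float(r[1]) if r[1] != "-inf" else -np.inf for r in rows]
    )
    support = np.array([r[2] == "1" for r in rows])
    return DensityOfStates(es, log_g, gauge, support, None, conv, iters)


def write_curves_tsv(curves, path) -> None:
    lines = [
        f"# window={curves.window}",
        f"# polyorder={curves.polyorder}",
        f"# trimmed={curves.trimmed[0]},{curves.trimmed[1]}",
        "E\tS\tbeta\tgamma\tdelta\td4",
    ]
    for i in range(len(curves.energies)):
        lines.append(
            f"{curves.energies[i]:.6f}\t{curves.s[i]:.10e}\t"
            f"{curves.beta[i]:.10e}\t{curves.gamma[i]:.10e}\t"
            f"{curves.delta[i]:.10e}\t{curves.s4[i]:.10e}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def write_prevalence_tsv(fieldv, path) -> None:
    lines = ["E\tq\tp"]
    for a in range(len(fieldv.energies)):
        for b in range(len(fieldv.q_values)):
            if not fieldv.mask[a, b]:
                lines.append(
                    f"{fieldv.energies[a]:.6f}\t{fieldv.q_values[b]:.6f}\t"
                    f"{fieldv.p[a, b]:.10e}"
                )
    _atomic_write(path, "\n".join(lines) + "\n")


def write_transitions_json(records, path) -> None:
    data = [
        {
            "energy": r.energy,
            "order": r.order,
            "channel": r.channel,
            "prominence": r.prominence,
            "s_tau": None if np.isnan(r.s_tau) else r.s_tau,
            "n": r.n,
        }
        for r in records
    ]
    _atomic_write(path, json.dumps(data, indent=1))


def persist_tables(objects: dict, out_dir, cfg: RunConfig | None = None) -> dict:
    """Write a mapping of relative-name -> object and return the manifest.

    Dispatches on object type (histograms, densities of states, entropy
    curves, transition lists, prevalence fields).  The manifest records
    every file written plus the config hash, seed, and software version.
    """
    from .microcanonical import EntropyCurves
    from .prevalence import PrevalenceField
    from .reweight import DensityOfStates

    os.makedirs(out_dir, exist_ok=True)
    files = []
    for name, obj in objects.items():
        path = os.path.join(out_dir, name)
        if isinstance(obj, EnergyHistogram):
            write_histogram_tsv(obj, path)
        elif isinstance(obj, DensityOfStates):
            write_dos_tsv(obj, path)
        elif isinstance(obj, EntropyCurves):
            write_curves_tsv(obj, path)
        elif isinstance(obj, PrevalenceField):
            write_prevalence_tsv(obj, path)
        elif isinstance(obj, list):
            write_transitions_json(obj, path)
        elif isinstance(obj, (dict, str)):
            _atomic_write(
                path, obj if isinstance(obj, str) else json.dumps(obj, indent=1)
            )
        else:
            raise TypeError(f"cannot persist object of type {type(obj)!r}")
        files.append(name)
    cfg_dict = cfg.to_dict() if cfg else {}
    manifest = {
        "version": __version__,
        "seed": cfg.seed if cfg else None,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=float).encode()
        ).hexdigest(),
        "files": files,
    }
    _atomic_write(
        os.path.join(out_dir, "manifest.json"), json.dumps(manifest, indent=1)
    )
    return manifest


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def pipeline_run(cfg: RunConfig, progress: bool = False) -> dict:
    """simulate -> reweight -> microcanonical analysis -> prevalence.

    Produces, per ``s_tau`` value: the per-thread histograms, the 1D and
    2D densities of states, entropy curves, the transition report, the
    prevalence field, and canonical mean-energy / specific-heat tables.
    Returns a results dict; all artifacts are persisted under
    ``cfg.out_dir`` with a manifest.
    """
    stage = "simulate"
    try:
        sched = cfg.build_schedule()
        grid = run_grid(sched, progress=progress)
        objects: dict = {}
        results = {"schedule": sched, "grid": grid, "per_s_tau": {}}
        for it in range(len(sched.temperatures)):
            for js in range(len(sched.s_tau_values)):
                objects[f"hist_T{it:02d}_S{js:02d}.tsv"] = grid.histograms[(it, js)]
        # per-thread move acceptance statistics
        stats_lines = ["T_index\ts_tau_index\tkind\taccepted\tattempted"]
        kinds = ("local", "global_displacement", "bend", "torsion")
        for (it, js), acc in sorted(grid.move_accepts.items()):
            att = grid.move_attempts[(it, js)]
            for k, name in enumerate(kinds):
                stats_lines.append(f"{it}\t{js}\t{name}\t{acc[k]}\t{att[k]}")
        objects["move_stats.tsv"] = "\n".join(stats_lines) + "\n"
        t_grid = np.linspace(
            sched.temperatures[0], sched.temperatures[-1], 200
        )
        for js, s_tau in enumerate(sched.s_tau_values):
            stage = f"reweight (s_tau={s_tau})"
            dos, zset, _ = wham(grid.column(js))
            dos2d = wham_2d(grid.joint_column(js))
            stage = f"analyze (s_tau={s_tau})"
            counts = np.sum([h.counts for h in grid.column(js)], axis=0)
            curves, transitions = analyze_dos(
                dos, cfg.window, cfg.polyorder, cfg.prominence_threshold,
                cfg.edge_trim, s_tau=s_tau, n=sched.n, counts=counts,
                beta_range=(1.0 / sched.temperatures[-1],
                            1.0 / sched.temperatures[0]),
            )
            stage = f"prevalence (s_tau={s_tau})"
            fieldv = prevalence_field(dos2d)
            e_mean, c_v = mean_energy_and_specific_heat(dos, t_grid)
            tag = f"S{js:02d}"
            objects[f"dos_{tag}.tsv"] = dos
            objects[f"dos2d_{tag}.tsv"] = dos2d
            objects[f"curves_{tag}.tsv"] = curves
            objects[f"transitions_{tag}.json"] = transitions
            objects[f"prevalence_{tag}.tsv"] = fieldv
            objects[f"canonical_{tag}.tsv"] = "\n".join(
                ["T\tE_mean\tC_V"]
                + [
                    f"{t:.6f}\t{e:.8e}\t{c:.8e}"
                    for t, e, c in zip(t_grid, e_mean, c_v)
                ]
            ) + "\n"
            results["per_s_tau"][float(s_tau)] = {
                "dos": dos,
                "dos2d": dos2d,
                "curves": curves,
                "transitions": transitions,
                "prevalence": fieldv,
                "temperatures": t_grid,
                "e_mean": e_mean,
                "c_v": c_v,
            }
        stage = "persist"
        results["manifest"] = persist_tables(objects, cfg.out_dir, cfg)
        # final lowest-temperature conformation per s_tau as XYZ snapshots
        from .model import order_parameter_q, write_xyz

        for js, s_tau in enumerate(sched.s_tau_values):
            st = grid.final_states[(0, js)]
            p = sched.params.with_s_tau(s_tau)
            write_xyz(
                os.path.join(cfg.out_dir, f"final_S{js:02d}.xyz"),
                st.coords,
                f"E={st.energy:.6f} q={order_parameter_q(st.coords, p):.6f} "
                f"s_tau={s_tau} T={sched.temperatures[0]}",
            )
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
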