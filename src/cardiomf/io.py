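"""Run configuration, snapshot archives and deterministic test fixtures.

Snapshot archive layout (single file, little-endian):

* magic ``b"CMFSNAP1"``;
* uint64 header length, then that many bytes of UTF-8 JSON with keys
  ``nx``, ``ny``, ``dx`` (mm), ``fields`` (channel names, stored order),
  ``dtype``, ``n_frames`` and an optional ``config`` mapping;
* float64 frame times (ms), n_frames values;
* the channels, each n_frames * ny * nx values, row-major, in ``fields``
  order.

Everything a run needs is expressible as a plain mapping and (de)serialized
through YAML, so a run is reproducible from its config file alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

_MAGIC = b"CMFSNAP1"

__all__ = ["SnapshotArchive", "RunConfig", "generate_fixture"]


@dataclass
class SnapshotArchive:
    """Time-ordered field frames plus the configuration that produced them."""

    t: np.ndarray                     # (n,) ms
    fields: dict                      # name -> (n, ny, nx) array
    dx: float
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, np.float64)
        n = self.t.size
        if n and np.any(np.diff(self.t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        shapes = {v.shape for v in self.fields.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent field shapes: {shapes}")
        for v in self.fields.values():
            if v.shape[0] != n:
                raise ValueError("field frame count does not match t")

    @property
    def shape(self):
        first = next(iter(self.fields.values()))
        return first.shape[1], first.shape[2]  # (ny, nx)

    def save(self, path) -> None:
        path = Path(path)
        ny, nx = self.shape
        dtype = str(next(iter(self.fields.values())).dtype)
        header = {
            "nx": nx, "ny": ny, "dx": self.dx,
            "fields": list(self.fields), "dtype": dtype,
            "n_frames": int(self.t.size), "config": self.config,
        }
        hb = json.dumps(header).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(np.uint64(len(hb)).tobytes())
            fh.write(hb)
            fh.write(self.t.astype("<f8").tobytes())
            for name in header["fields"]:
                fh.write(np.ascontiguousarray(self.fields[name]).tobytes())

    @classmethod
    def load(cls, path) -> "SnapshotArchive":
        with open(path, "rb") as fh:
            if fh.read(8) != _MAGIC:
                raise ValueError(f"{path} is not a snapshot archive")
            (hlen,) = np.frombuffer(fh.read(8), "<u8")
            header = json.loads(fh.read(int(hlen)).decode())
            n, ny, nx = header["n_frames"], header["ny"], header["nx"]
            t = np.frombuffer(fh.read(8 * n), "<f8").copy()
            fields = {}
            itemsize = np.dtype(header["dtype"]).itemsize
            for name in header["fields"]:
                raw = fh.read(itemsize * n * ny * nx)
                fields[name] = np.frombuffer(raw, header["dtype"]) \
                    .reshape(n, ny, nx).copy()
        return cls(t, fields, header["dx"], header.get("config", {}))


@dataclass
class RunConfig:
    """Serializable description of a run; schema-checked on load."""

    protocol: str = "plane_wave"      # plane_wave | spiral | inhomogeneity | control | single_cell
    coupling_mode: str = "zero_sided"
    D: float = 0.00154
    G_gap: float = 0.0
    G_ff: float = 0.0
    G_mf: float = 0.0
    C_f: float = 6.3
    G_f: float = 4.0
    E_f: float = -49.0
    N_f: int = 1
    ny: int = 7
    nx: int = 600
    dx: float = 0.225
    dt: float = 0.02
    t_end: float = 500.0
    snapshot_every_ms: float = 8.0
    output_dir: str = "."

    _PROTOCOLS = ("plane_wave", "spiral", "inhomogeneity", "control",
                  "single_cell")

    def validate(self) -> "RunConfig":
        if self.protocol not in self._PROTOCOLS:
            raise ValueError(f"config field 'protocol': {self.protocol!r} "
                             f"not in {self._PROTOCOLS}")
        for name in ("D", "G_gap", "G_ff", "G_mf", "C_f", "G_f", "dt", "dx"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v < 0 \
                    or not math.isfinite(v):
                raise ValueError(f"config field {name!r}: must be a "
                                 f"non-negative finite number, got {v!r}")
        if self.N_f < 0 or self.ny < 3 or self.nx < 3:
            raise ValueError("config fields N_f/ny/nx out of range")
        return self

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data).validate()

    def coupling(self):
        from .params import FibroblastParams
        from .tissue import CouplingConfig
        return CouplingConfig(mode=self.coupling_mode, D=self.D,
                              G_gap=self.G_gap, G_ff=self.G_ff,
                              G_mf=self.G_mf, G_fm=self.G_mf,
                              fib=FibroblastParams(self.C_f, self.G_f,
                                                   self.E_f))


def save_grid_state(grid, path, extra: dict | None = None) -> None:
    """Persist a full BilayerGrid state (float64) as a snapshot archive."""
    fields = {"V_m": grid.Vm[None].astype(np.float64),
              "V_f": grid.Vf[None].astype(np.float64),
              "ggap": grid.ggap[None].astype(np.float64),
              "fib_mask": grid.fib_mask[None].astype(np.float64)}
    for k in range(16):
        fields[f"state_{k}"] = grid.G[k][None].astype(np.float64)
    cfg = {"kind": "grid-state", "dx": grid.dx, "t": grid.t}
    cfg.update(extra or {})
    SnapshotArchive(np.array([grid.t if grid.t > 0 else 1.0]),
                    fields, grid.dx, cfg).save(path)


def load_grid_state(path):
    """Inverse of :func:`save_grid_state`; returns (BilayerGrid, config)."""
    from .tissue import BilayerGrid
    arch = SnapshotArchive.load(path)
    if arch.config.get("kind") != "grid-state":
        raise ValueError(f"{path} is not a grid-state archive")
    vm = arch.fields["V_m"][0]
    ny, nx = vm.shape
    g = BilayerGrid(ny, nx, dx=arch.dx,
                    fib_mask=arch.fields["fib_mask"][0].astype(np.uint8))
    g.Vm = vm.copy()
    g.Vf = arch.fields["V_f"][0].copy()
    g.ggap = arch.fields["ggap"][0].copy()
    for k in range(16):
        g.G[k] = arch.fields[f"state_{k}"][0]
    g.t = float(arch.config.get("t", 0.0))
    return g, arch.config


# ------------------------------------------------------------------ fixtures

_MAX_FIXTURE_NODES = 400 * 400


def generate_fixture(kind: str, size: int = 60, dx: float = 0.225,
                     frames: int = 12, **kw) -> SnapshotArchive:
    """Deterministic archives for tests.

    kinds: ``resting-strip`` (constant resting fields), ``plane-wave-strip``
    (a short propagating-front run), ``synthetic-rotor-field`` (analytic
    Archimedean spiral of activation values with a known core -- no ODEs;
    core coordinates recorded in the archive config), ``small-spiral``
    (an actual scaled spiral-initiation run; expensive).
    """
    if size * size > _MAX_FIXTURE_NODES:
        raise ValueError(f"fixture size {size} exceeds the desk budget")
    if kind == "resting-strip":
        from .params import INITIAL_STATE
        ny, nx = max(size // 8, 3), size
        t = 8.0 * np.arange(frames)
        vm = np.full((frames, ny, nx), INITIAL_STATE[0], np.float32)
        return SnapshotArchive(t, {"V_m": vm}, dx, {"kind": kind})

    if kind == "plane-wave-strip":
        # tall enough that the swept-front band is a vertical locus whose
        # skeleton terminates on the domain border
        from .tissue import BilayerGrid, CouplingConfig, StimulusEvent, run_tissue
        ny, nx = max(size // 2, 9), size
        g = BilayerGrid(ny, nx, dx=dx, fib_mask=np.zeros((ny, nx)))
        stim = StimulusEvent.rectangle((ny, nx), 0.0, 3.0, -150.0,
                                       cols=slice(0, 3))
        # snapshots start after the stimulus transient so every frame shows
        # an established (or absent) front
        # 2 ms cadence keeps the swept I_Na band a thin (elongated) locus
        res = run_tissue(g, CouplingConfig(mode="zero_sided"), [stim],
                         t_end=16.0 + frames * 2.0, snap_every_ms=2.0,
                         snap_t0=16.0, snap_fields=("V_m", "I_Na"))
        return SnapshotArchive(res.t_snap,
                               {"V_m": res.snap_Vm, "I_Na": res.snap_INa},
                               dx, {"kind": kind})

    if kind == "synthetic-rotor-field":
        core = kw.get("core", ((size // 2) * dx, (size // 2) * dx))
        period = kw.get("period", 160.0)       # ms
        pitch = kw.get("pitch", 12.0 * dx)     # radial turn spacing, mm
        amp = kw.get("amplitude", 400.0)
        t = 8.0 * np.arange(frames)
        yy, xx = np.mgrid[0:size, 0:size] * dx
        r = np.hypot(xx - core[0], yy - core[1])
        th = np.arctan2(yy - core[1], xx - core[0])
        stack = np.zeros((frames, size, size), np.float32)
        # phase distance 2*pi corresponds to one radial pitch, so a constant
        # phase half-width gives a line ~1.5 nodes thick; the arm runs from
        # just outside the core to beyond the tracked border
        halfw = min(np.pi * 1.5 * dx / pitch, 0.6)
        for k, tk in enumerate(t):
            phase = th - 2 * np.pi * (r / pitch - tk / period)
            wrapped = np.angle(np.exp(1j * phase))
            line = (np.abs(wrapped) < halfw) & (r > 0.75 * dx)
            stack[k][line] = amp
        return SnapshotArchive(t, {"I_Na": stack}, dx,
                               {"kind": kind, "core": list(core),
                                "period": period})

    if kind == "small-spiral":
        from .analysis import sodium_threshold
        from .protocols import SpiralInitProtocol, initiate_spiral
        from .tissue import CouplingConfig, run_tissue
        proto = SpiralInitProtocol.scaled(size)
        grid, _tips = initiate_spiral(proto)
        res = run_tissue(grid, CouplingConfig(mode="zero_sided", D=proto.D),
                         [], t_end=frames * 8.0, snap_every_ms=8.0,
                         snap_fields=("V_m", "I_Na"))
        return SnapshotArchive(res.t_snap,
                               {"V_m": res.snap_Vm, "I_Na": res.snap_INa},
                               dx, {"kind": kind,
                                    "threshold": sodium_threshold(grid.myo)})

    raise ValueError(f"unknown fixture kind {kind!r}")
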