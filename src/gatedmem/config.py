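"""Run configuration, deterministic seeding, fixtures, and result I/O."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "spawn_seeds",
    "make_fixture",
    "save_results",
    "save_network",
    "load_network",
]

_EXPERIMENTS = ("simulate", "phase", "dmft", "flow")

#: default Euler step per experiment
_DEFAULT_DT = {"simulate": 0.2, "phase": 0.2, "dmft": 0.02, "flow": 0.25}


class ConfigError(ValueError):
    """Invalid run configuration; message lists the offending keys."""


@dataclass
class RunConfig:
    """Validated parameters for one experiment run.

    Defaults are the reference operating point of the model: N = 1000,
    g = 1.5, tau_z = 1, horizon T = 2000, Euler step 0.2 for network
    integration (0.02 for DMFT, 0.25 for flow maps).
    """

    experiment: str = "simulate"
    N: int = 1000
    P: int | None = None
    alpha: float | None = None
    gamma: float = 0.0
    g: float = 1.5
    tau_z: float = 1.0
    dt: float | None = None
    T: float = 2000.0
    m0: float = 0.55
    M: int = 5000
    tol: float = 1e-3
    reps: int = 100
    seed: int = 0
    out: str | None = None
    reference_scale: bool = False

    def __post_init__(self) -> None:
        bad = []
        if self.experiment not in _EXPERIMENTS:
            bad.append(f"experiment={self.experiment!r} (choose from {_EXPERIMENTS})")
        if isinstance(self.gamma, str):
            if self.gamma.lower() in ("inf", "infinity", "binary"):
                self.gamma = np.inf
            else:
                try:
                    self.gamma = float(self.gamma)
                except ValueError:
                    bad.append(f"gamma={self.gamma!r}")
        if self.dt is None:
            self.dt = _DEFAULT_DT.get(self.experiment, 0.2)
        if self.alpha is not None and self.P is None:
            self.P = int(round(self.alpha * self.N))
            self.alpha = self.P / self.N
        elif self.P is not None:
            self.alpha = self.P / self.N
        if self.N < 2:
            bad.append(f"N={self.N}")
        if self.P is not None and self.P < 1:
            bad.append(f"P={self.P}")
        if not (isinstance(self.gamma, str) or self.gamma >= 0):
            bad.append(f"gamma={self.gamma}")
        for key in ("g", "tau_z", "dt", "T", "tol"):
            if getattr(self, key) <= 0:
                bad.append(f"{key}={getattr(self, key)}")
        if self.reps < 1 or self.M < 1:
            bad.append(f"reps={self.reps}, M={self.M}")
        if bad:
            raise ConfigError("invalid configuration keys: " + "; ".join(bad))

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["gamma"], float) and np.isinf(d["gamma"]):
            d["gamma"] = "inf"
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a JSON file and/or keyword flags.

    Flags override file values; unknown keys raise ConfigError.
    """
    data: dict = {}
    if path is not None:
        data.update(json.loads(Path(path).read_text()))
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**data)


def spawn_seeds(root_seed: int, n: int, label: str = "") -> list[int]:
    """Deterministic per-component child seeds (< 2**31) from one root seed."""
    label_int = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    entropy = [root_seed] + ([label_int] if label else [])
    ss = np.random.SeedSequence(entropy)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(name: str, seed: int = 0) -> dict:
    """Deterministic tiny instances used across the test suite.

    ``ungated_retrieval``: N=50, P=3, gamma=0 retrieval run inputs.
    ``gated_overload``:    N=50, P=20, binary gate, overload regime.
    ``orthogonal_pair``:   N=100, P=2 exact orthogonal pattern pair.
    ``dmft_linear_toy``:   small exponential-kernel response test system.
    """
    from .model import make_network, make_orthogonal_pair

    seeds = spawn_seeds(seed, 4, name)
    if name == "ungated_retrieval":
        spec = make_network(50, 3, gamma=0.0, seed=seeds[0])
        return {"spec": spec, "m0": 0.8, "dt": 0.2, "T": 200.0}
    if name == "gated_overload":
        spec = make_network(50, 20, gamma=np.inf, seed=seeds[0])
        return {"spec": spec, "m0": 0.6, "dt": 0.2, "T": 200.0}
    if name == "orthogonal_pair":
        pair = make_orthogonal_pair(100, np.random.default_rng(seeds[0]))
        return {"patterns": pair}
    if name == "dmft_linear_toy":
        n, dt, lam = 40, 0.1, 0.7
        R = np.tril(np.full((n, n), 0.0), -1)
        np.fill_diagonal(R[1:, :-1], -lam / dt)  # memoryless decay kernel
        return {"R": R, "dt": dt, "lam": lam, "n": n}
    raise ValueError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# quenched-disorder serialization


def save_network(spec, path: str | Path) -> None:
    """Persist one quenched-disorder realization to a self-describing .npz.

    Stored keys: patterns, kind, W (empty if absent), seed, N, P, and the
    scalar model parameters.
    """
    path = Path(path)
    np.savez(
        path,
        patterns=spec.patterns.patterns,
        kind=spec.patterns.kind,
        W=spec.W if spec.W is not None else np.empty((0, 0)),
        seed=-1 if spec.seed is None else spec.seed,
        N=spec.N,
        P=spec.P,
        g=spec.g,
        gamma=spec.gamma,
        tau_z=spec.tau_z,
    )


def load_network(path: str | Path):
    """Inverse of :func:`save_network`."""
    from .model import NetworkSpec, PatternSet

    with np.load(Path(path).with_suffix(".npz"), allow_pickle=False) as d:
        W = d["W"] if d["W"].size else None
        seed = int(d["seed"])
        return NetworkSpec(
            patterns=PatternSet(d["patterns"], str(d["kind"])),
            g=float(d["g"]),
            gamma=float(d["gamma"]),
            tau_z=float(d["tau_z"]),
            W=W,
            seed=None if seed == -1 else seed,
        )


# ---------------------------------------------------------------------------
# result serialization


def save_results(record: dict, path: str | Path) -> dict:
    """Persist a result record and return its manifest.

    Arrays go to ``<path>.npz``, DataFrames to ``<path>_<key>.csv``, and a
    manifest JSON (config, seed, content hash) to ``<path>_manifest.json``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {k: v for k, v in record.items() if isinstance(v, np.ndarray)}
    frames = {k: v for k, v in record.items() if isinstance(v, pd.DataFrame)}
    scalars = {
        k: v
        for k, v in record.items()
        if not isinstance(v, (np.ndarray, pd.DataFrame, RunConfig))
    }
    manifest: dict = {"files": [], "scalars": scalars}
    cfg = record.get("config")
    if isinstance(cfg, RunConfig):
        manifest["config"] = cfg.to_dict()
        manifest["config_hash"] = cfg.digest()
        manifest["seed"] = cfg.seed
    try:
        if arrays:
            np.savez(path.with_suffix(".npz"), **arrays)
            manifest["files"].append(path.with_suffix(".npz").name)
        for key, df in frames.items():
            f = path.parent / f"{path.name}_{key}.csv"
            df.to_csv(f, index=False)
            manifest["files"].append(f.name)
        mpath = path.parent / f"{path.name}_manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
    except OSError as err:
        raise OSError(f"failed writing results under {path}: {err}") from err
    return manifest
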