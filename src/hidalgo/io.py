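"""Delimited-text readers and result writers for the command line.

Inputs are plain numeric tables (comma or tab separated, optional header),
either coordinates (rows = points) or a square distance matrix.  Outputs
are CSV/JSON files carrying the hard labels, the membership probabilities,
the posterior summary, the log-posterior trace, and a run manifest with
enough information (config, seeds, input checksum, software version) to
re-run bit-identically.  Floats are serialized with shortest round-trip
precision (17 significant digits), so reloading reproduces them exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .model import HidalgoConfig
from .sampler import FitResult

__all__ = ["read_matrix", "write_results", "read_labels"]


def read_matrix(
    path,
    delimiter: str | None = None,
    header: str = "auto",
    distances: bool = False,
) -> np.ndarray:
    """Load a delimited numeric matrix; validates a distance matrix.

    The header row is auto-detected (first row non-numeric).  A distance
    matrix must be square with zero diagonal; asymmetry within 1e-9 is
    symmetrized with a warning, anything larger is an error.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else None
    try:
        df = pd.read_csv(path, sep=sep, header=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path}: {exc}") from exc
    first_numeric = pd.to_numeric(df.iloc[0], errors="coerce")
    if first_numeric.isna().any():
        df = df.iloc[1:].reset_index(drop=True)
    if header == "yes" and not first_numeric.isna().any():
        df = df.iloc[1:].reset_index(drop=True)
    try:
        x = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(x).any():
        raise ValueError(f"{path} contains missing or non-numeric cells")
    if distances:
        n = x.shape[0]
        if x.shape[1] != n:
            raise ValueError(f"distance matrix must be square, got {x.shape}")
        asym = np.max(np.abs(x - x.T))
        if asym > 1e-9:
            raise ValueError(f"distance matrix asymmetric (max deviation {asym:.3g})")
        if asym > 0:
            import warnings

            warnings.warn("symmetrizing slightly asymmetric distance matrix", stacklevel=2)
            x = 0.5 * (x + x.T)
        if np.max(np.abs(np.diag(x))) > 1e-9:
            raise ValueError("distance matrix diagonal must be zero")
        np.fill_diagonal(x, 0.0)
    return x


def read_labels(path) -> np.ndarray:
    """Integer label vector from a one-column (or labels-column) CSV."""
    df = pd.read_csv(path)
    col = "label" if "label" in df.columns else df.columns[-1]
    return df[col].to_numpy(dtype=np.int64)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_dict(cfg: HidalgoConfig) -> dict:
    return {
        "K": cfg.K,
        "q": cfg.q,
        "xi": cfg.xi,
        "a": cfg.a.tolist(),
        "b": cfg.b.tolist(),
        "c": cfg.c.tolist(),
        "n_sweeps": cfg.n_sweeps,
        "keep_fraction": cfg.keep_fraction,
        "n_chains": cfg.n_chains,
        "seed": cfg.seed,
        "assignment_threshold": cfg.assignment_threshold,
    }


def write_results(fit: FitResult, outdir, input_path=None) -> dict:
    """Write labels.csv, pi.csv, summary.json, trace.csv and manifest.json."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = fit.pi.shape[0]
    max_pi = fit.pi.max(axis=1)

    labels = pd.DataFrame(
        {"point_id": np.arange(n), "label": fit.labels, "max_pi": max_pi}
    )
    labels.to_csv(outdir / "labels.csv", index=False, float_format="%.17g")

    pd.DataFrame(fit.pi, columns=[f"pi_{k}" for k in range(1, fit.K + 1)]).to_csv(
        outdir / "pi.csv", index=False, float_format="%.17g"
    )

    summary = {
        "K": fit.K,
        "d_mean": fit.d_mean.tolist(),
        "d_sd": fit.d_sd.tolist(),
        "p_mean": fit.p_mean.tolist(),
        "L": fit.L,
        "best_chain": fit.best_chain,
        "n_unassigned": fit.n_unassigned,
        "config": _config_dict(fit.config),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))

    best = fit.traces[fit.best_chain] if fit.traces else None
    if best is not None:
        np.savetxt(
            outdir / "trace.csv",
            best.log_posterior,
            fmt="%.17g",
            header="log_posterior",
            comments="",
        )

    manifest = {
        "software": {"name": "hidalgo", "version": __version__},
        "config": _config_dict(fit.config),
        "chain_seeds": [fit.config.seed + j for j in range(fit.config.n_chains)],
        "input": {
            "path": str(input_path) if input_path else None,
            "sha256": _sha256(input_path) if input_path else None,
        },
        "chains": {
            "mean_log_posterior": fit.diagnostics.get("mean_log_posterior"),
            "max_log_posterior": fit.diagnostics.get("max_log_posterior"),
            "best_chain": fit.best_chain,
            "n_label_switches": fit.diagnostics.get("n_label_switches"),
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
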