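"""File formats, pipeline configuration and the end-to-end driver.

Formats (all plain text):

* dense matrix CSV — header row of region ids, N data rows in the same
  order (no index column);
* edge-list TSV — columns region_a, region_b, weight; undirected, each
  pair listed once (a duplicate pair with a conflicting weight is an
  error);
* label TSV — columns region_id, system;
* tidy profile TSV — one row per region x subject x scan, columns
  region_id, subject, scan, avg_ctrl, modal_ctrl, boundary_ctrl,
  global_ctrl, degree.

Every table written by the pipeline starts with ``#``-comment header
lines recording the master seed, so each output is reproducible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boundary import BoundaryParams
from .generator import (
    GeneratorParams,
    SystemLabels,
    generate_cohort,
    generate_system_labels,
)
from .network import Connectome, stabilize

__all__ = [
    "PROFILE_COLUMNS",
    "PipelineConfig",
    "read_connectome",
    "write_connectome",
    "read_labels",
    "write_labels",
    "read_profiles",
    "write_profiles",
    "run_pipeline",
]

log = logging.getLogger("netctrl")

PROFILE_COLUMNS = [
    "region_id",
    "subject",
    "scan",
    "avg_ctrl",
    "modal_ctrl",
    "boundary_ctrl",
    "global_ctrl",
    "degree",
]

_SYM_TOL = 1e-9


def read_connectome(path, fmt: str | None = None) -> Connectome:
    """Read a network from dense CSV or edge-list TSV (inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "dense" if path.suffix.lower() == ".csv" else "edgelist"
    if fmt == "dense":
        df = pd.read_csv(path, comment="#")
        ids = [str(c) for c in df.columns]
        A = df.to_numpy(dtype=float)
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"{path}: dense matrix is {A.shape[0]}x{A.shape[1]}")
        if np.any(A < 0):
            raise ValueError(f"{path}: negative weights")
        if not np.allclose(A, A.T, atol=_SYM_TOL, rtol=0):
            raise ValueError(f"{path}: matrix asymmetric beyond {_SYM_TOL}")
        A = (A + A.T) / 2.0
        if np.any(np.diag(A) != 0):
            log.warning("%s: nonzero diagonal forced to 0", path)
            np.fill_diagonal(A, 0.0)
        return Connectome(region_ids=ids, adjacency=A)
    if fmt == "edgelist":
        df = pd.read_csv(path, sep="\t", comment="#")
        need = {"region_a", "region_b", "weight"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: edge list needs columns {sorted(need)}")
        seen: dict[tuple[str, str], float] = {}
        for a, b, w in zip(df["region_a"], df["region_b"], df["weight"]):
            a, b, w = str(a), str(b), float(w)
            if w < 0:
                raise ValueError(f"{path}: negative weight on ({a}, {b})")
            if a == b:
                log.warning("%s: self-loop on %s dropped", path, a)
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen and seen[key] != w:
                raise ValueError(
                    f"{path}: conflicting duplicate edge {key}: {seen[key]} vs {w}"
                )
            seen[key] = w
        ids = sorted({r for k in seen for r in k})
        idx = {r: i for i, r in enumerate(ids)}
        A = np.zeros((len(ids), len(ids)))
        for (a, b), w in seen.items():
            A[idx[a], idx[b]] = A[idx[b], idx[a]] = w
        return Connectome(region_ids=ids, adjacency=A)
    raise ValueError(f"unknown connectome format {fmt!r}")


def _write_text(path: Path, header: list[str], body: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write(body)


def write_connectome(conn: Connectome, path, fmt: str | None = None,
                     seed: int | None = None) -> Path:
    path = Path(path)
    if fmt is None:
        fmt = "dense" if path.suffix.lower() == ".csv" else "edgelist"
    header = [] if seed is None else [f"seed={seed}"]
    if fmt == "dense":
        df = pd.DataFrame(conn.adjacency, columns=conn.region_ids)
        _write_text(path, header, df.to_csv(index=False, float_format="%.10g"))
    elif fmt == "edgelist":
        i, j = np.nonzero(np.triu(conn.adjacency, 1))
        df = pd.DataFrame(
            {
                "region_a": [conn.region_ids[a] for a in i],
                "region_b": [conn.region_ids[b] for b in j],
                "weight": conn.adjacency[i, j],
            }
        )
        _write_text(path, header, df.to_csv(sep="\t", index=False, float_format="%.10g"))
    else:
        raise ValueError(f"unknown connectome format {fmt!r}")
    return path


def write_labels(labels: SystemLabels, path, seed: int | None = None) -> Path:
    df = pd.DataFrame(
        sorted(labels.labels.items()), columns=["region_id", "system"]
    )
    header = [] if seed is None else [f"seed={seed}"]
    _write_text(Path(path), header, df.to_csv(sep="\t", index=False))
    return Path(path)


def read_labels(path) -> SystemLabels:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SystemLabels(
        labels={str(r): str(s) for r, s in zip(df["region_id"], df["system"])}
    )


def write_profiles(profiles: pd.DataFrame, path, seed: int | None = None) -> Path:
    """Tidy profile TSV; round-trips exactly through :func:`read_profiles`."""
    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise ValueError(f"profile table missing columns {missing}")
    header = [] if seed is None else [f"seed={seed}"]
    body = profiles[PROFILE_COLUMNS].to_csv(sep="\t", index=False)
    _write_text(Path(path), header, body)
    return Path(path)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"region_id": str, "subject": str, "scan": str})
    return df[PROFILE_COLUMNS] if len(df) else df


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; serializable to YAML."""

    generator: GeneratorParams = field(default_factory=GeneratorParams)
    n_subjects: int = 8
    n_scans: int = 3
    input_connectomes: list[str] | None = None  # overrides the generator
    input_labels: str | None = None
    scheme: str = "spectral"
    c: float = 1.0
    boundary: BoundaryParams = field(default_factory=BoundaryParams)
    k_hubs: int = 30
    degree_mode: str = "sum"
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorParams(**raw.pop("generator", {}))
        bnd = BoundaryParams(**raw.pop("boundary", {}))
        return cls(generator=gen, boundary=bnd, **raw)

    def to_yaml(self, path) -> Path:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
        return Path(path)


def _versions() -> dict[str, str]:
    import igraph
    import leidenalg
    import scipy

    from . import __version__

    return {
        "netctrl": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "igraph": igraph.__version__,
        "leidenalg": leidenalg.version,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """generate/ingest -> stabilize -> profiles -> cohort tables.

    Writes profiles.tsv, mean_ranks.tsv, hubs.tsv, enrichment.tsv,
    hub_means.tsv, correlations.tsv, labels.tsv, a YAML manifest and a log
    into ``config.outdir``.  Identical config + seed reproduce every table
    byte for byte.
    """
    from .cohort import analyze_cohort
    from .gramian import control_profile

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(fh)
    try:
        return _run_pipeline_inner(config, out)
    except Exception:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _run_pipeline_inner(config: PipelineConfig, out: Path) -> Path:
    from .cohort import analyze_cohort
    from .gramian import control_profile

    seed = config.seed
    gen = dataclasses.replace(config.generator, seed=seed)
    boundary = dataclasses.replace(config.boundary, seed=seed)

    log.info("stage ingest: acquiring cohort")
    if config.input_connectomes:
        cohort = [read_connectome(p) for p in config.input_connectomes]
    else:
        cohort = generate_cohort(gen, config.n_subjects, config.n_scans)
    n = cohort[0].n
    if config.input_labels:
        labels = read_labels(config.input_labels)
    else:
        labels = generate_system_labels(n, seed=seed)
    write_labels(labels, out / "labels.tsv", seed=seed)

    log.info("stage profiles: %d scans of %d regions", len(cohort), n)
    frames = []
    for conn in cohort:
        try:
            sys = stabilize(conn, scheme=config.scheme, c=config.c)
            frames.append(
                control_profile(
                    conn, sys, boundary_params=boundary,
                    degree_mode=config.degree_mode,
                )
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage profiles failed on subject={conn.subject} "
                f"scan={conn.scan}: {exc}"
            ) from exc
    profiles = pd.concat(frames, ignore_index=True)
    write_profiles(profiles, out / "profiles.tsv", seed=seed)

    log.info("stage cohort: aggregating %d rows", len(profiles))
    res = analyze_cohort(profiles, labels, k=config.k_hubs)
    hdr = [f"seed={seed}"]
    _write_text(out / "mean_ranks.tsv", hdr,
                res.mean_ranks.to_csv(sep="\t", float_format="%.10g"))
    hub_df = pd.DataFrame(
        [
            {"diagnostic": d, "rank": i + 1, "region_id": r}
            for d, regions in res.hubs.items()
            for i, r in enumerate(regions)
        ]
    )
    _write_text(out / "hubs.tsv", hdr, hub_df.to_csv(sep="\t", index=False))
    _write_text(out / "enrichment.tsv", hdr,
                res.enrichment.to_csv(sep="\t", index=False, float_format="%.10g"))
    _write_text(out / "hub_means.tsv", hdr,
                res.hub_means.to_csv(sep="\t", index=False, float_format="%.10g"))
    _write_text(out / "correlations.tsv", hdr,
                res.correlations.to_csv(sep="\t", index=False, float_format="%.10g"))

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": seed,
        "n_networks": len(cohort),
        "n_regions": n,
        "versions": _versions(),
    }
    with open(out / "manifest.yaml", "w") as mh:
        yaml.safe_dump(manifest, mh, sort_keys=True)
    log.info("pipeline complete: %s", out)
    return out
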