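"""End-to-end pipeline driver: cloud -> smooth -> normals -> reconstruct ->
volume (-> weight), with validated configuration and a JSON report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from cloudvol.geometry import read_point_cloud, write_mesh
from cloudvol.poisson import ScreenedConfig, reconstruct
from cloudvol.smoothing import MlsConfig
from cloudvol.volume import mesh_volume
from cloudvol.weight import WeightModel, predict_weight

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

_TRUE = {"1", "true", "yes", "on"}


@dataclass
class PipelineConfig:
    """Validated parameters of the full pipeline run."""

    input: str = ""
    output_mesh: str = "mesh.ply"
    output_report: str = "report.json"
    smooth: bool = True
    smooth_k: int = 30
    smooth_basis: str = "quadratic"
    smooth_bandwidth: float = 2.0
    k_pca: int = 20
    k_graph: int = 10
    depth: int = 8
    method: str = "improved"
    lam: float = 4.0
    tau_neighbors: int = 10
    tol: float = 1e-8
    weight_model: str = ""  # optional JSON model for weight prediction
    seed: int = 0

    def validate(self) -> tuple[MlsConfig, ScreenedConfig]:
        """Check every stage's preconditions before any work starts."""
        if not self.input:
            raise ValueError("input path is required")
        if self.method not in ("poisson", "improved"):
            raise ValueError(f"method must be 'poisson' or 'improved', got {self.method!r}")
        if self.k_pca < 3:
            raise ValueError("k_pca must be >= 3")
        if self.k_graph < 1:
            raise ValueError("k_graph must be >= 1")
        mls = MlsConfig(k=self.smooth_k, basis=self.smooth_basis, bandwidth=self.smooth_bandwidth)
        screened = ScreenedConfig(
            lam=self.lam, n_weight_neighbors=self.tau_neighbors, depth=self.depth, tol=self.tol
        )
        return mls, screened

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from JSON or flat ``key=value`` text."""
        text = Path(path).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            raw = json.loads(text)
        else:
            raw = {}
            for lineno, line in enumerate(text.splitlines(), 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, val = line.split("=", 1)
                raw[key.strip()] = val.strip()
        known = {f.name: f.type for f in fields(cls)}
        cfg = cls()
        for key, val in raw.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                val = val if isinstance(val, bool) else str(val).lower() in _TRUE
            elif isinstance(current, int):
                val = int(val)
            elif isinstance(current, float):
                val = float(val)
            else:
                val = str(val)
            setattr(cfg, key, val)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return (and write) the report."""
    mls, screened = config.validate()  # fail fast, before any I/O or compute

    t0 = time.perf_counter()
    cloud = read_point_cloud(config.input)
    report: dict = {"input": config.input, "n_points": len(cloud)}
    mesh = reconstruct(
        cloud,
        depth=config.depth,
        method=config.method,
        config=screened,
        smooth=config.smooth,
        mls_config=mls,
        k_pca=config.k_pca,
        k_graph=config.k_graph,
        report=report,
    )
    result = mesh_volume(mesh)
    report.update(
        {
            "volume": result.volume,
            "signed_raw": result.signed_raw,
            "facet_count": result.facet_count,
            "lambda": config.lam,
            "seed": config.seed,
        }
    )
    if config.weight_model:
        model = WeightModel.from_json(Path(config.weight_model).read_text())
        report["predicted_weight_kg"] = predict_weight(model, result.volume)
    report["total_seconds"] = time.perf_counter() - t0

    write_mesh(mesh, config.output_mesh)
    Path(config.output_report).write_text(json.dumps(report, indent=2))
    log.info("pipeline done: volume=%.6g, %d facets", result.volume, result.facet_count)
    return report


def config_to_dict(config: PipelineConfig) -> dict:
    return asdict(config)
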