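"""End-to-end workflow: simulate/load → superpose → matrix → project (PCA +
random replicates) → cross-validate clusters → figures + manifest.

Every source of randomness derives deterministically from one top-level seed:
the ensemble generator uses the seed itself and random-projection replicate r
uses ``seed + 1_000_000 + r`` (consecutive seeds across replicates), so a
manifest pins the whole run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .structures import (
    CoordinateMatrix,
    build_matrix,
    common_atom_set,
    read_calpha,
    superpose_ensemble,
    write_matrix,
)
from .projection import (
    ProjectionResult,
    StandardizedMatrix,
    pca_project,
    random_project,
    standardize,
)
from .synthetic import EnsembleRecipe, simulate_ensemble, write_pdb
from .validation import (
    ClusterReport,
    best_replicate_report,
    confidence_ellipse,
    detect_clusters,
    flag_outliers,
)

__all__ = [
    "PipelineError",
    "RunManifest",
    "AnalysisResult",
    "RANDOM_SEED_OFFSET",
    "replicate_seed",
    "analyze_matrix",
    "ensemble_to_matrix",
    "run_pipeline",
    "write_scores",
    "read_scores",
]

RANDOM_SEED_OFFSET = 1_000_000


def replicate_seed(seed: int, replicate: int) -> int:
    return seed + RANDOM_SEED_OFFSET + replicate


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    seed: int
    replicate_seeds: list
    matrix_shape: tuple
    pca_spectrum: list
    random_spectrum: list
    n_clusters_pca: int
    n_clusters_random: int
    agreement: float
    verdict: str
    version: str = __version__

    def to_json(self) -> str:
        payload = asdict(self)
        payload["matrix_shape"] = list(self.matrix_shape)
        return json.dumps(payload, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class AnalysisResult:
    standardized: StandardizedMatrix
    pca: ProjectionResult
    random_used: ProjectionResult
    report: ClusterReport
    replicate_seeds: list


def ensemble_to_matrix(structures, reference: str = "iterative_mean") -> CoordinateMatrix:
    """Shared-atom intersection, superposition, and matrix construction."""
    keys = common_atom_set(structures)
    fitted = superpose_ensemble(structures, keys, reference=reference)
    return build_matrix(fitted, keys)


def analyze_matrix(
    matrix: CoordinateMatrix,
    seed: int,
    k: int = 2,
    replicates: int = 1,
    detector: str = "kmeans_silhouette",
    threshold: float = 0.9,
    force_k_pca: int | None = None,
    detector_params: dict | None = None,
) -> AnalysisResult:
    """Standardize, project with both methods, and cross-validate clusters.

    With ``replicates`` > 1 the random projection is redrawn with consecutive
    seeds; the verdict is validated as soon as one replicate reproduces the
    PCA partition (a single random 2-frame can miss a real separation
    direction, so replication reduces false negatives). Replicates stop early
    at the first validated draw.
    """
    params = detector_params or {}
    std = standardize(matrix)
    pca = pca_project(std, k=k)
    assignment_pca = detect_clusters(
        pca.scores, method=detector, force_k=force_k_pca, **params
    )

    seeds, assignments, projections = [], [], []
    best = None
    for r in range(max(1, replicates)):
        s = replicate_seed(seed, r)
        proj = random_project(std, seed=s, k=k)
        assignment = detect_clusters(proj.scores, method=detector, **params)
        seeds.append(s)
        assignments.append(assignment)
        projections.append(proj)
        report = best_replicate_report(assignment_pca, [assignment], threshold)
        if best is None or report.verdict == "validated" or (
            best.verdict != "validated" and report.agreement > best.agreement
        ):
            best = report
            best_proj = proj
        if report.verdict == "validated":
            break
    return AnalysisResult(std, pca, best_proj, best, seeds)


def write_scores(result: ProjectionResult, path) -> None:
    with open(path, "w") as handle:
        cols = "\t".join(f"component_{i + 1}" for i in range(result.k))
        handle.write(f"entry_id\t{cols}\n")
        labels = result.row_labels or [f"row{i}" for i in range(len(result.scores))]
        for label, row in zip(labels, result.scores):
            handle.write(str(label) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_scores(path) -> tuple:
    labels, rows = [], []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if not header or header[0] != "entry_id":
            raise ValueError(f"{path}: malformed scores header")
        for line in handle:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            labels.append(cells[0])
            rows.append([float(c) for c in cells[1:]])
    return labels, np.array(rows)


# --- full pipeline ----------------------------------------------------------

_DEFAULTS = {
    "seed": 0,
    "output_dir": "ensembleproj_run",
    "superpose": {"reference": "iterative_mean"},
    "project": {"k": 2, "replicates": 1},
    "validate": {
        "detector": "kmeans_silhouette",
        "threshold": 0.9,
        "force_k_pca": None,
        "ellipse_levels": [0.95, 0.99],
    },
    "plot": True,
}


def _merged_config(config: dict) -> dict:
    merged = json.loads(json.dumps(_DEFAULTS))
    for section, value in config.items():
        if isinstance(value, dict) and isinstance(merged.get(section), dict):
            merged[section].update(value)
        else:
            merged[section] = value
    return merged


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    return wrap


def load_config(path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config


def run_pipeline(config) -> RunManifest:
    """Execute every stage of the workflow from a config mapping or YAML path.

    The config needs either a ``simulate`` section (synthetic ensemble) or an
    ``input.pdb_dir`` pointing at PDB files. Outputs (matrix, scores, report,
    figure, manifest) land in ``output_dir``.
    """
    if not isinstance(config, dict):
        config = _stage("config")(load_config, config)
    cfg = _merged_config(config)
    seed = int(cfg["seed"])
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    true_labels = None
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        write_pdbs = sim.pop("write_pdbs", False)
        recipe = _stage("simulate")(EnsembleRecipe, seed=seed, **sim)
        ensemble = _stage("simulate")(simulate_ensemble, recipe)
        structures, true_labels = ensemble.structures, ensemble.true_labels
        if write_pdbs:
            pdb_dir = out / "pdbs"
            pdb_dir.mkdir(exist_ok=True)
            for s in structures:
                _stage("simulate")(write_pdb, s, pdb_dir / f"{s.entry_id}.pdb")
    elif "input" in cfg:
        inp = cfg["input"]
        pdb_dir = Path(inp["pdb_dir"])
        paths = sorted(pdb_dir.glob("*.pdb")) + sorted(pdb_dir.glob("*.ent"))
        if not paths:
            raise PipelineError("input", FileNotFoundError(f"no PDB files in {pdb_dir}"))
        structures = [
            _stage("input")(
                read_calpha,
                p,
                chain_filter=inp.get("chains"),
                altloc_policy=inp.get("altloc", "highest_occupancy"),
            )
            for p in paths
        ]
    else:
        raise PipelineError(
            "config", ValueError("config needs a 'simulate' or 'input' section")
        )

    matrix = _stage("superpose")(
        ensemble_to_matrix, structures, reference=cfg["superpose"]["reference"]
    )
    _stage("superpose")(write_matrix, matrix, out / "matrix.tsv")

    vcfg = cfg["validate"]
    analysis = _stage("project")(
        analyze_matrix,
        matrix,
        seed=seed,
        k=int(cfg["project"]["k"]),
        replicates=int(cfg["project"]["replicates"]),
        detector=vcfg["detector"],
        threshold=float(vcfg["threshold"]),
        force_k_pca=vcfg.get("force_k_pca"),
    )
    _stage("project")(write_scores, analysis.pca, out / "scores_pca.tsv")
    _stage("project")(write_scores, analysis.random_used, out / "scores_random.tsv")

    report = analysis.report
    report_payload = {
        "verdict": report.verdict,
        "agreement": report.agreement,
        "threshold": report.threshold,
        "labels_pca": report.assignment_pca.labels.tolist(),
        "labels_random": report.assignment_random.labels.tolist(),
        "detector": vcfg["detector"],
        "outlier_flags": flag_outliers(analysis.pca.scores).tolist(),
        "ellipses": _stage("validate")(
            _cluster_ellipses,
            analysis.pca.scores,
            report.assignment_pca.labels,
            vcfg["ellipse_levels"],
        ),
    }
    if true_labels is not None:
        report_payload["true_labels"] = np.asarray(true_labels).tolist()
    (out / "report.json").write_text(json.dumps(report_payload, indent=2))

    if cfg.get("plot", True):
        from .plotting import plot_projections

        _stage("plot")(
            plot_projections,
            analysis.pca,
            analysis.random_used,
            report,
            out / "projections.png",
            ellipse_levels=vcfg["ellipse_levels"],
        )

    manifest = RunManifest(
        config=cfg,
        seed=seed,
        replicate_seeds=analysis.replicate_seeds,
        matrix_shape=matrix.shape,
        pca_spectrum=np.asarray(analysis.pca.spectrum).tolist(),
        random_spectrum=np.asarray(analysis.random_used.spectrum).tolist(),
        n_clusters_pca=report.assignment_pca.n_clusters,
        n_clusters_random=report.assignment_random.n_clusters,
        agreement=report.agreement,
        verdict=report.verdict,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _cluster_ellipses(scores, labels, levels):
    ellipses = []
    for cluster in sorted(set(labels) - {-1}):
        pts = scores[labels == cluster]
        if len(pts) < 3:
            continue
        for level in levels:
            try:
                e = confidence_ellipse(pts, level)
            except ValueError:
                continue
            ellipses.append(
                {
                    "cluster": int(cluster),
                    "level": level,
                    "center": e.center.tolist(),
                    "semi_axes": e.semi_axes.tolist(),
                    "angle": e.angle,
                }
            )
    return ellipses
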