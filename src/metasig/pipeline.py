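"""End-to-end pipeline: data (synthetic or loaded) -> rank selection ->
factorization -> sample clustering -> per-signature enrichment ->
differential table, with a JSON run manifest recording configuration,
seeds, per-stage wall time and outputs for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .consensus import select_rank
from .differential import fold_change
from .enrich import enrich_signature
from .exceptions import ConfigurationError, EmptyHitsError, PipelineStageError
from .matrix import MetaboliteMatrix
from .nmf import factorize
from .signatures import cluster_samples, dominant_signature, top_metabolites
from .simulate import StudyConfig, generate_pathway_library, generate_study

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("metasig")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either the three file paths (``matrix_path``
    required; groups and GMT optional) or a synthetic :class:`StudyConfig`.
    """

    matrix_path: str | None = None
    groups_path: str | None = None
    gmt_path: str | None = None
    synthetic: StudyConfig | None = None
    synthetic_pathways: int = 20  # pathways generated alongside synthetic data
    synthetic_pathway_sizes: tuple[int, int] = (5, 30)
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    n_runs: int = 50
    base_seed: int = 0
    objective: str = "frobenius"
    top_q: float = 0.5
    test: str = "student_t"
    distance: str = "correlation"
    cut_k: int = 2
    out_dir: str = "metasig_out"

    def __post_init__(self) -> None:
        if (self.matrix_path is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of matrix_path or synthetic must be supplied"
            )
        if self.matrix_path is None and (self.groups_path or self.gmt_path):
            raise ConfigurationError(
                "groups_path/gmt_path only apply with matrix_path input"
            )
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        if not self.k_candidates:
            raise ConfigurationError("k_candidates must be non-empty")
        if not (0 < self.top_q <= 1):
            raise ConfigurationError("top_q must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under ``out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Stage failures are re-raised as :class:`PipelineStageError` carrying
    the stage name; stages completed so far stay on disk and the manifest
    flags the run as partial.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "metasig",
        "version": metadata.version("metasig"),
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
        "complete": False,
    }
    state: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                outputs = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(manifest, out)
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": outputs,
            }
            log.info("stage %s: done (%s)", name, outputs)

        return deco

    @stage("data")
    def _data():
        if config.synthetic is not None:
            matrix, truth = generate_study(config.synthetic)
            library = generate_pathway_library(
                config.synthetic_pathways,
                config.synthetic_pathway_sizes,
                truth,
                planted=[
                    (i, sig)
                    for i, sig in enumerate(
                        sorted(config.synthetic.group_signature_map.values())
                    )
                ],
                seed=config.synthetic.seed,
            )
            state.update(matrix=matrix, truth=truth, library=library)
            msio.write_matrix(matrix, out / "matrix.tsv")
            msio.write_groups(matrix.group_labels, out / "groups.tsv")
            msio.write_gmt(library, out / "pathways.gmt")
            truth.true_signatures.to_csv(out / "truth_signatures.tsv", sep="\t")
            truth.true_loadings.to_csv(out / "truth_loadings.tsv", sep="\t")
            return [
                "matrix.tsv", "groups.tsv", "pathways.gmt",
                "truth_signatures.tsv", "truth_loadings.tsv",
            ]
        labels = msio.read_groups(config.groups_path) if config.groups_path else None
        matrix = msio.read_matrix(config.matrix_path, group_labels=labels)
        state["matrix"] = matrix
        if config.gmt_path:
            state["library"] = msio.read_gmt(config.gmt_path)
        return []

    @stage("select_rank")
    def _rank():
        res = select_rank(
            state["matrix"],
            config.k_candidates,
            n_runs=config.n_runs,
            base_seed=config.base_seed,
            objective=config.objective,
        )
        state["rank"] = res
        curve = pd.DataFrame(
            {"k": list(res.cophenetic_by_k), "cophenetic": list(res.cophenetic_by_k.values())}
        )
        curve.to_csv(out / "cophenetic_by_k.tsv", sep="\t", index=False)
        res.consensus_by_k[res.chosen_k].consensus.to_csv(
            out / "consensus.tsv", sep="\t"
        )
        manifest["chosen_k"] = res.chosen_k
        return ["cophenetic_by_k.tsv", "consensus.tsv"]

    @stage("factorize")
    def _factorize():
        res = factorize(
            state["matrix"],
            k=state["rank"].chosen_k,
            objective=config.objective,
            seed=config.base_seed,
        )
        state["fit"] = res
        res.signatures.weights.to_csv(out / "signatures.tsv", sep="\t")
        res.loadings.loadings.to_csv(out / "loadings.tsv", sep="\t")
        return ["signatures.tsv", "loadings.tsv"]

    @stage("dominant")
    def _dominant():
        table = dominant_signature(state["fit"].loadings)
        table.to_csv(out / "dominant_signature.tsv", sep="\t")
        return ["dominant_signature.tsv"]

    @stage("cluster")
    def _cluster():
        matrix = state["matrix"]
        groups = matrix.groups() if matrix.group_labels else None
        ca = cluster_samples(
            state["fit"].loadings,
            distance=config.distance,
            cut_k=config.cut_k,
            groups=groups,
        )
        ca.flat_labels.to_csv(out / "clusters.tsv", sep="\t")
        (out / "dendrogram.nwk").write_text(
            msio.linkage_to_newick(ca.merge_tree, ca.sample_ids) + "\n"
        )
        manifest["purity_by_group"] = ca.purity_by_group
        # direct-clustering coefficient, for comparison with the
        # consensus-based one used in rank selection
        manifest["direct_cophenetic"] = ca.cophenetic
        return ["clusters.tsv", "dendrogram.nwk"]

    @stage("top_metabolites")
    def _top():
        outputs = []
        for name in state["fit"].signatures.signature_names:
            table = top_metabolites(state["fit"].signatures, name, q=config.top_q)
            fname = f"top_metabolites_{name}.tsv"
            table.to_csv(out / fname, sep="\t")
            outputs.append(fname)
        return outputs

    @stage("enrichment")
    def _enrich():
        if "library" not in state:
            return []
        outputs = []
        for name in state["fit"].signatures.signature_names:
            try:
                table = enrich_signature(
                    state["fit"].signatures, name, state["library"], q=config.top_q
                )
            except EmptyHitsError:
                continue
            fname = f"enrichment_{name}.tsv"
            table.to_csv(out / fname, sep="\t", index=False)
            outputs.append(fname)
        return outputs

    @stage("differential")
    def _diff():
        matrix = state["matrix"]
        if not matrix.group_labels:
            return []
        table = fold_change(matrix, test=config.test)
        table.to_csv(out / "differential.tsv", sep="\t")
        return ["differential.tsv"]

    manifest["complete"] = all(
        s["status"] == "ok" for s in manifest["stages"].values()
    )
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
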