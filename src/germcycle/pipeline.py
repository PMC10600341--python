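"""Reproducible end-to-end runs: simulate -> qc -> cell-cycle scoring ->
proportion statistics (and optionally image -> N/C ratios), with a
machine-readable manifest and a small human-readable report.

A run is driven by a single :class:`RunConfig` (YAML-serializable; unknown
keys are rejected) and one seed; two runs with the same config and seed
produce byte-identical result CSVs and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from germcycle import __version__
from germcycle.cellcycle import (
    AssignParams,
    compare_proportions,
    phase_proportions,
    score_and_assign,
)
from germcycle.imaging import quantify_image
from germcycle.io import write_counts, write_image
from germcycle.qc import filter_cells, lognormalize
from germcycle.simulate import ImageSpec, SimDesign, simulate_cell_image, simulate_counts


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``.stage``."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _build(cls, params: Mapping[str, Any] | None, what: str):
    params = dict(params or {})
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(params) - allowed
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**params)


@dataclass
class RunConfig:
    """Full configuration of a pipeline run."""

    seed: int = 0
    simulate: dict = field(default_factory=dict)   # SimDesign overrides
    images: dict | None = None                      # ImageSpec overrides
    min_genes: int = 200
    assign: dict = field(default_factory=dict)      # AssignParams overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return _build(cls, raw, "run config")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    def design(self) -> SimDesign:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        return _build(SimDesign, params, "simulate")

    def image_spec(self) -> ImageSpec | None:
        if self.images is None:
            return None
        params = dict(self.images)
        params.setdefault("seed", self.seed + 1)
        return _build(ImageSpec, params, "images")

    def assign_params(self) -> AssignParams:
        return _build(AssignParams, self.assign, "assign")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages, writing outputs, a manifest, and a report.

    Any stage failure writes a ``FAILED`` marker naming the stage (partial
    outputs are retained) and raises :class:`StageError`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # validate everything before running any stage
    design = config.design()
    design.validate()
    spec = config.image_spec()
    params = config.assign_params()

    outputs: dict[str, Path] = {}
    stage = "simulate"
    try:
        adata, genesets = simulate_counts(design)
        counts_dir = write_counts(adata, outdir / "counts")
        genesets.to_gmt(outdir / "genesets.gmt")
        outputs["genesets"] = outdir / "genesets.gmt"

        stage = "qc"
        filtered = filter_cells(adata, min_genes=config.min_genes)
        expr = lognormalize(filtered)
        qc_report = dict(filtered.uns["qc"])
        (outdir / "qc_report.json").write_text(
            json.dumps(qc_report, indent=2, sort_keys=True)
        )
        outputs["qc_report"] = outdir / "qc_report.json"

        stage = "cellcycle"
        labels = score_and_assign(expr, genesets, params)
        labels.insert(0, "group", expr.obs["group"].to_numpy())
        labels.to_csv(outdir / "labels.csv", index_label="cell_id")
        outputs["labels"] = outdir / "labels.csv"
        props = phase_proportions(labels["label"], labels["group"])
        props.to_csv(outdir / "proportions.csv")
        outputs["proportions"] = outdir / "proportions.csv"
        _plot_proportions(props, outdir / "proportions.png")

        stage = "stats"
        stats_out: dict[str, Any] = {}
        if props.shape[0] >= 2:
            chi2, dof, p = compare_proportions(props)
            stats_out["proportion_chi2"] = {
                "statistic": chi2, "dof": dof, "pvalue": p,
            }
        (outdir / "stats.json").write_text(
            json.dumps(stats_out, indent=2, sort_keys=True)
        )
        outputs["stats"] = outdir / "stats.json"

        ratios = None
        if spec is not None:
            stage = "images"
            image, truth = simulate_cell_image(spec)
            write_image(image, outdir / "image.tif", truth)
            stage = "ncr"
            ratios = quantify_image(image)
            ratios.to_csv(outdir / "nc_ratios.csv", index=False)
            outputs["nc_ratios"] = outdir / "nc_ratios.csv"

        stage = "report"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                "simulate": dataclasses.asdict(design),
                "images": dataclasses.asdict(spec) if spec else None,
                "min_genes": config.min_genes,
                "assign": dataclasses.asdict(params),
            },
            "inputs": {"counts": str(counts_dir.name)},
            "checksums": {
                name: _sha256(path)
                for name, path in sorted(outputs.items())
                if path.suffix in {".csv", ".json", ".gmt"}
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        _write_report(outdir / "report.txt", qc_report, props, ratios)
    except Exception as exc:  # noqa: BLE001 - marker + named re-raise
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc
    return outdir


def _plot_proportions(props, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prop_cols = [c for c in props.columns if c.startswith("prop_")]
    ax = props[prop_cols].rename(
        columns=lambda c: c.removeprefix("prop_")
    ).plot(kind="bar", stacked=True, figsize=(6, 4), colormap="viridis")
    ax.set_ylabel("proportion of cells")
    ax.set_title("cell cycle status by group")
    ax.legend(bbox_to_anchor=(1.02, 1), loc="upper left")
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()


def _write_report(path: Path, qc_report, props, ratios) -> None:
    lines = ["germcycle run report", "=" * 40, ""]
    lines.append(
        f"QC: {qc_report['n_cells_after']}/{qc_report['n_cells_before']} "
        f"cells kept (>{qc_report['min_genes']} genes)"
    )
    lines.append("")
    lines.append("Cell cycle status proportions by group:")
    lines.append(props.to_string(float_format=lambda v: f"{v:.4f}"))
    if ratios is not None:
        ok = ratios.dropna(subset=["ratio"])
        lines.append("")
        lines.append(
            f"N/C ratios: {len(ok)} cells quantified; "
            f"median ratio {ok['ratio'].median():.3f}"
            if len(ok) else "N/C ratios: no cells quantified"
        )
    path.write_text("\n".join(lines) + "\n")
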