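"""Config-driven orchestration of the whole workflow.

One run generates (or loads) the spot spectra, filters/averages/normalises
them, masks resonance regions, chains colours, assembles and fuses blocks,
and then evaluates every requested method (PCA, NMF, ComDim-PCA, ComDim-ICA)
on every dataset (LIBS, Raman, LIBS+Raman) and masking stratum (raw,
shortened), reporting total explained variance, the best silhouette plane
and the multidimensional silhouette per combination.  PCA of the fused block
is SUM-PCA.  All randomness derives from one root seed through fixed-purpose
seed-sequence children, so every stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from . import synthetic as syn
from .decompose import Decomposition, comdim, nmf, pca
from .evaluate import scan_planes, subspace_silhouette
from .synthetic import LIBS, RAMAN, COLOURS, StudyDesign

log = logging.getLogger("planktofuse")

METHODS = ("PCA", "NMF", "ComDim-PCA", "ComDim-ICA")
DATASETS = (LIBS, RAMAN, "LIBS+Raman")
STRATA = ("raw", "shortened")
LABEL_SCHEMES = ("four-taxa", "crustacea-merged", "calanoida-vs-euphausiacea")

# fixed stage indices of the seed-derivation scheme
_STAGE_GENERATE, _STAGE_NMF, _STAGE_ICA = 0, 1, 2


def derive_seed(root_seed: int, stage: int) -> int:
    """Stage seed from the root seed: child ``stage`` of the root
    SeedSequence, folded below 2**31."""
    child = np.random.SeedSequence(root_seed).spawn(stage + 1)[stage]
    return int(child.generate_state(1, np.uint32)[0] >> 1)


@dataclass
class RunConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    mask_regions: list[pp.MaskRegion] = field(
        default_factory=pp.default_mask_regions
    )
    grubbs_alpha: float = 0.05
    grubbs_windows: list[pp.PeakWindow] = field(
        default_factory=pp.default_peak_windows
    )
    n_components: dict[str, int] = field(
        default_factory=lambda: {m: 6 for m in METHODS}
    )
    nmf_restarts: int = 20
    nmf_tol: float = 1e-6
    nmf_max_iter: int = 500
    silhouette_variant: str = "macro"
    label_schemes: dict[str, str] = field(
        default_factory=lambda: {
            LIBS: "calanoida-vs-euphausiacea",
            RAMAN: "crustacea-merged",
            "LIBS+Raman": "calanoida-vs-euphausiacea",
        }
    )
    methods: tuple = METHODS
    datasets: tuple = DATASETS
    masking: tuple = STRATA
    seed: int = 0
    outdir: str | None = None
    make_figures: bool = False

    def __post_init__(self) -> None:
        if any(p < 2 for p in self.n_components.values()):
            raise ValueError("component counts must be >= 2")
        for scheme in self.label_schemes.values():
            if scheme not in LABEL_SCHEMES:
                raise ValueError(f"unknown label scheme {scheme!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must specify a seed")
        kwargs = {}
        if "design" in raw:
            d = dict(raw["design"])
            for key in ("libs_grid", "raman_grid"):
                if key in d:
                    d[key] = tuple(d[key])
            d.setdefault("seed", raw["seed"])
            kwargs["design"] = StudyDesign(**d)
        else:
            kwargs["design"] = StudyDesign(seed=raw["seed"])
        if "mask_regions" in raw:
            kwargs["mask_regions"] = [
                pp.MaskRegion(**r) for r in raw["mask_regions"]
            ]
        for key in (
            "grubbs_alpha", "n_components", "nmf_restarts", "nmf_tol",
            "nmf_max_iter", "silhouette_variant", "label_schemes", "outdir",
            "make_figures",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("methods", "datasets", "masking"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(seed=raw["seed"], **kwargs)


@dataclass
class ReportRow:
    method: str
    dataset: str
    masking: str
    total_ev: float
    best_plane: tuple[int, int]
    best_plane_sil_pct: float
    multidim_sil_pct: float
    label_scheme: str


def apply_label_scheme(taxa: pd.Series, scheme: str):
    """Map sample taxa to cluster labels under one of the study's schemes;
    returns (boolean row mask, labels for the selected rows).  The mixed
    sample never enters a silhouette."""
    taxa = pd.Series(list(taxa))
    if scheme == "four-taxa":
        keep = taxa.isin(["Calanoida", "Euphausiacea", "Parasagitta", "Limacina"])
        labels = taxa[keep]
    elif scheme == "crustacea-merged":
        keep = taxa.isin(["Calanoida", "Euphausiacea", "Parasagitta", "Limacina"])
        labels = taxa[keep].replace(
            {"Calanoida": "Crustacea", "Euphausiacea": "Crustacea"}
        )
    elif scheme == "calanoida-vs-euphausiacea":
        keep = taxa.isin(["Calanoida", "Euphausiacea"])
        labels = taxa[keep]
    else:
        raise ValueError(f"unknown label scheme {scheme!r}")
    return keep.to_numpy(), labels.to_numpy()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def preprocess_dataset(
    spectra: list[syn.Spectrum],
    windows: list[pp.PeakWindow],
    alpha: float,
) -> tuple[dict[tuple[str, str, str], syn.Spectrum], pd.DataFrame]:
    """Grubbs-filter (LIBS), total-intensity normalise (Raman) and average
    the spots of every (sample, colour, modality) group.

    Returns the averaged spectra keyed by (sample_id, colour, modality) and a
    per-group log of removed-spot counts.
    """
    groups: dict[tuple[str, str, str], list[syn.Spectrum]] = {}
    order: list[tuple[str, str, str]] = []
    for s in spectra:
        key = (s.sample_id, s.colour, s.modality)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)

    averaged: dict[tuple[str, str, str], syn.Spectrum] = {}
    log_rows = []
    for key in order:
        sample_id, colour, modality = key
        spots = groups[key]
        if modality == LIBS:
            kept = pp.filter_spots(spots, windows, alpha)
            mean = pp.average_spots(kept)
        else:
            kept = spots
            mean = pp.average_spots([pp.normalize_total(s) for s in spots])
        averaged[key] = mean
        log_rows.append(
            {
                "sample_id": sample_id,
                "colour": colour,
                "modality": modality,
                "n_spots": len(spots),
                "n_removed": len(spots) - len(kept),
            }
        )
    removal_log = pd.DataFrame(log_rows)
    log.info(
        "preprocess: %d groups, %d spots removed by Grubbs",
        len(order),
        int(removal_log.n_removed.sum()),
    )
    return averaged, removal_log


def build_blocks(
    averaged: dict[tuple[str, str, str], syn.Spectrum],
    sample_ids: list[str],
) -> dict[str, pp.DataBlock]:
    """Chain the three colour spectra of each sample and stack samples into
    one block per modality."""
    blocks = {}
    for modality in (LIBS, RAMAN):
        vectors = []
        feature_axis = None
        for sample_id in sample_ids:
            triple = {
                colour: averaged[(sample_id, colour, modality)]
                for colour in COLOURS
            }
            values, features = pp.chain_colours(
                triple["dark"], triple["medium"], triple["light"]
            )
            vectors.append((sample_id, values))
            feature_axis = features
        blocks[modality] = pp.assemble_block(vectors, feature_axis, modality)
        log.info("block %s: %s", modality, blocks[modality].shape)
    return blocks


def _clip_negatives(matrix: np.ndarray) -> tuple[np.ndarray, int]:
    n_neg = int((matrix < 0).sum())
    return (np.clip(matrix, 0.0, None), n_neg) if n_neg else (matrix, 0)


def decompose_dataset(
    method: str,
    dataset: str,
    blocks: dict[str, pp.DataBlock],
    config: RunConfig,
):
    """Run one method on one dataset; returns (scores, total EV, extras)."""
    p = config.n_components[method]
    if method in ("ComDim-PCA", "ComDim-ICA"):
        parts = (
            [blocks[LIBS], blocks[RAMAN]]
            if dataset == "LIBS+Raman"
            else [blocks[dataset]]
        )
        result = comdim(parts, p, inner_method=method.split("-")[1].lower())
        weights = np.array([np.linalg.norm(b.matrix) ** 2 for b in parts])
        total_ev = float(result.block_ev @ (weights / weights.sum()))
        return result.Q, total_ev, result
    block = (
        pp.fuse_blocks([blocks[LIBS], blocks[RAMAN]])
        if dataset == "LIBS+Raman"
        else blocks[dataset]
    )
    if method == "PCA":
        dec = pca(block, p)
        return dec.scores, dec.total_ev, dec
    if method == "NMF":
        matrix, n_clipped = _clip_negatives(block.matrix)
        if n_clipped:
            log.info("NMF %s/%s: clipped %d negative cells", method, dataset,
                     n_clipped)
        nn_block = pp.DataBlock(
            matrix=matrix,
            row_ids=list(block.row_ids),
            feature_axis=block.feature_axis,
            block_name=block.block_name,
            frobenius_norm_applied=block.frobenius_norm_applied,
        )
        dec = nmf(
            nn_block,
            p,
            n_restarts=config.nmf_restarts,
            seed=derive_seed(config.seed, _STAGE_NMF),
            tol=config.nmf_tol,
            max_iter=config.nmf_max_iter,
        )
        return dec.scores, dec.total_ev, dec
    raise ValueError(f"unknown method {method!r}")


def run_pipeline(config: RunConfig):
    """End-to-end run; returns (report DataFrame, artifacts dict).

    The report has one row per method x dataset x masking stratum with the
    total explained variance, the best silhouette plane and the
    multidimensional silhouette over all retained components, each computed
    on the dataset's configured cluster-label scheme.
    """
    design = config.design
    if design.seed != config.seed:
        design = StudyDesign(**{**asdict(design), "seed": config.seed})
    spectra, metadata = syn.generate_dataset(design)
    log.info("generate: %d spot spectra", len(spectra))

    averaged, removal_log = preprocess_dataset(
        spectra, config.grubbs_windows, config.grubbs_alpha
    )
    sample_ids = list(dict.fromkeys(metadata.sample_id))
    taxa = metadata.drop_duplicates("sample_id").set_index("sample_id").taxon
    taxa = taxa.loc[sample_ids]

    raw_blocks = build_blocks(averaged, sample_ids)
    strata: dict[str, dict[str, pp.DataBlock]] = {}
    if "raw" in config.masking:
        strata["raw"] = raw_blocks
    if "shortened" in config.masking:
        strata["shortened"] = {
            mod: pp.apply_mask(b, config.mask_regions)
            for mod, b in raw_blocks.items()
        }

    rows = []
    decompositions = {}
    for stratum, blocks in strata.items():
        for dataset in config.datasets:
            scheme = config.label_schemes[dataset]
            keep, labels = apply_label_scheme(taxa, scheme)
            for method in config.methods:
                scores, total_ev, extra = decompose_dataset(
                    method, dataset, blocks, config
                )
                scan = scan_planes(
                    scores[keep], labels, config.silhouette_variant
                )
                multi = subspace_silhouette(
                    scores[keep],
                    range(1, scores.shape[1] + 1),
                    labels,
                    config.silhouette_variant,
                )
                rows.append(
                    ReportRow(
                        method=method,
                        dataset=dataset,
                        masking=stratum,
                        total_ev=float(total_ev),
                        best_plane=scan.best_plane,
                        best_plane_sil_pct=100.0 * scan.best_sil,
                        multidim_sil_pct=100.0 * multi,
                        label_scheme=scheme,
                    )
                )
                decompositions[(method, dataset, stratum)] = extra
                log.info(
                    "%s | %s | %s: EV=%.3f best plane %s Sil=%.1f%%",
                    method, dataset, stratum, total_ev, scan.best_plane,
                    100.0 * scan.best_sil,
                )

    report = pd.DataFrame(
        [
            {
                "method": r.method,
                "dataset": r.dataset,
                "masking": r.masking,
                "total_ev": r.total_ev,
                "best_plane": f"{r.best_plane[1]}-{r.best_plane[0]}",
                "best_plane_sil_pct": r.best_plane_sil_pct,
                "multidim_sil_pct": r.multidim_sil_pct,
                "label_scheme": r.label_scheme,
            }
            for r in rows
        ]
    )
    artifacts = {
        "metadata": metadata,
        "removal_log": removal_log,
        "blocks": strata,
        "decompositions": decompositions,
        "taxa": taxa,
    }
    if config.outdir:
        _write_artifacts(config, report, artifacts)
    return report, artifacts


def _write_artifacts(config: RunConfig, report: pd.DataFrame, artifacts) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir / "report.csv", index=False, float_format="%.10g")
    artifacts["removal_log"].to_csv(outdir / "removal_log.csv", index=False)
    blocks_dir = outdir / "blocks"
    blocks_dir.mkdir(exist_ok=True)
    for stratum, blocks in artifacts["blocks"].items():
        for modality, block in blocks.items():
            stem = f"{modality.lower()}_{stratum}"
            pd.DataFrame(block.matrix, index=block.row_ids).to_csv(
                blocks_dir / f"{stem}.csv", float_format="%.8g"
            )
            sidecar = {
                "block_name": block.block_name,
                "frobenius_norm_applied": block.frobenius_norm_applied,
                "provenance": block.provenance,
                "n_features": int(block.shape[1]),
            }
            (blocks_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    if config.make_figures:
        from .plots import save_run_figures

        save_run_figures(config, report, artifacts, outdir / "figures")


def mask_li_experiment(config: RunConfig):
    """Rerun the (shortened) pipeline with and without additional masking of
    the Li I 610.4/670.8 nm lines and report the silhouette differences.

    The comparison addresses whether the taxon discrimination is driven by
    the anomalous Li content of the copepods or survives without it.
    """
    base_report, base_art = run_pipeline(config)
    li_config = RunConfig(
        **{
            **{f: getattr(config, f) for f in config.__dataclass_fields__},
            "mask_regions": list(config.mask_regions) + pp.li_mask_regions(),
        }
    )
    li_report, li_art = run_pipeline(li_config)
    keys = ["method", "dataset", "masking"]
    delta = base_report[keys].copy()
    delta["sil_pct_without_li_mask"] = base_report.best_plane_sil_pct
    delta["sil_pct_with_li_mask"] = li_report.best_plane_sil_pct
    delta["sil_pct_delta"] = (
        li_report.best_plane_sil_pct - base_report.best_plane_sil_pct
    )
    return {
        "base_report": base_report,
        "li_masked_report": li_report,
        "delta": delta,
        "base_artifacts": base_art,
        "li_artifacts": li_art,
    }
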