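"""End-to-end orchestration: simulate-or-load → QC/normalize → purity →
differential expression/gradients → spot trends → integration.

:func:`analyze_bundle` runs the analysis stages on an in-memory bundle and
returns all intermediate results; :func:`run_pipeline` wraps it with file
I/O, a JSON run manifest (config echo, input hashes, per-stage summaries)
and deterministic outputs given a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .design import DEFAULT_TAU
from .differential import (
    gradient_change_table,
    gradient_profiles,
    pca_overview,
    run_comparisons,
)
from .dige import annotate_trends, profiles_from_spots, records_from_frame, select_candidate_spots
from .errors import ConfigurationError
from .fraction_purity import MarkerTable, read_marker_table, score_and_select, write_selection
from .integration import integrate, read_target_map
from .qpcr import global_mean_normalize, read_cp_matrix, to_linear_signal
from .synthetic_data import (
    Bundle,
    SimConfig,
    generate_bundle,
    null_type_i_rate,
    pair_recovery,
    planted_de_recall,
    write_bundle,
)

log = logging.getLogger("cryptvillus")


@dataclass
class RunConfig:
    """One pipeline run: either a simulation config or input paths.

    ``inputs`` maps table names (cp_matrix, sample_groups, markers, spots,
    target_map) to TSV paths.  Thresholds default to the panel/DIGE
    conventions: p < 0.05, signal > 500, candidate spot cutoff 1.75,
    selected-spot cutoff 2.0, gradient threshold τ = 1.45.
    """

    outdir: str = "cryptvillus-run"
    simulate: SimConfig | None = None
    inputs: dict[str, str] | None = None
    tau: float = DEFAULT_TAU
    alpha: float = 0.05
    signal_threshold: float = 500.0
    signal_scale: float = 32768.0
    candidate_fold_cutoff: float = 1.75
    selected_fold_cutoff: float = 2.0
    combine_rule: str = "union"
    pca_top_k: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.tau <= 1:
            raise ConfigurationError(f"tau must exceed 1, got {self.tau}")
        for name in ("alpha", "signal_threshold", "signal_scale",
                     "candidate_fold_cutoff", "selected_fold_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "provide exactly one of a simulation config or input paths"
            )


def _load_bundle(cfg: RunConfig) -> Bundle:
    paths = cfg.inputs
    required = {"cp_matrix", "sample_groups", "markers", "spots", "target_map"}
    missing = required - set(paths or {})
    if missing:
        raise ConfigurationError(f"missing input paths: {sorted(missing)}")
    cp = read_cp_matrix(paths["cp_matrix"], paths["sample_groups"])
    markers = read_marker_table(paths["markers"])
    spots = records_from_frame(
        annotate_trends(pd.read_csv(paths["spots"], sep="\t", comment="#",
                                    dtype={"spot_id": str}))
    )
    tmap = read_target_map(paths["target_map"], combine_rule=cfg.combine_rule)
    from .synthetic_data import GroundTruth

    truth = GroundTruth(de_mirnas={}, true_pairs=set(), fraction_purity=[])
    return Bundle(config=SimConfig(seed=cfg.seed), cp_matrix=cp,
                  marker_table=markers, spot_records=spots,
                  target_map=tmap, ground_truth=truth)


def analyze_bundle(
    bundle: Bundle,
    *,
    alpha: float = 0.05,
    signal_threshold: float = 500.0,
    signal_scale: float | None = None,
    tau: float = DEFAULT_TAU,
    pca_top_k: int = 50,
) -> dict:
    """Run every analysis stage on a bundle; returns a dict of results."""
    if signal_scale is None:
        signal_scale = bundle.config.signal_anchor
    norm = global_mean_normalize(bundle.cp_matrix)
    signal = to_linear_signal(norm.values, scale=signal_scale)
    de_table = run_comparisons(
        signal, bundle.cp_matrix.groups,
        alpha=alpha, signal_threshold=signal_threshold,
    )
    mirna_profiles = gradient_profiles(signal, bundle.cp_matrix.groups, tau=tau)
    changes = gradient_change_table(mirna_profiles)
    coords, top_features = pca_overview(norm.values.dropna(how="any"), k=pca_top_k)
    purity = score_and_select(bundle.marker_table)
    protein_profiles = profiles_from_spots(bundle.spot_records, tau=tau)
    report = integrate(mirna_profiles, protein_profiles, bundle.target_map, tau=tau)
    return {
        "normalized": norm,
        "signal": signal,
        "de_table": de_table,
        "mirna_profiles": mirna_profiles,
        "gradient_changes": changes,
        "pca_coords": coords,
        "pca_features": top_features,
        "purity": purity,
        "protein_profiles": protein_profiles,
        "integration": report,
    }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a configured run and write all stage outputs plus a manifest.

    Outputs (TSV unless noted): normalized expression, per-comparison
    differential results, miRNA gradient profiles and change categories,
    PCA coordinates, fraction-purity selection, spot trends and candidate
    selections, the integration report, and ``manifest.json``.
    """
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    input_hashes = {}
    if cfg.simulate is not None:
        bundle = generate_bundle(cfg.simulate)
        write_bundle(bundle, out / "simulated_inputs")
        log.info("simulated bundle: %d miRNAs, %d proteins, seed %d",
                 cfg.simulate.n_mirna, cfg.simulate.n_protein, cfg.simulate.seed)
    else:
        bundle = _load_bundle(cfg)
        input_hashes = {k: _sha256(v) for k, v in sorted(cfg.inputs.items())}

    res = analyze_bundle(
        bundle, alpha=cfg.alpha, signal_threshold=cfg.signal_threshold,
        signal_scale=cfg.signal_scale if cfg.simulate is None else None,
        tau=cfg.tau, pca_top_k=cfg.pca_top_k,
    )

    res["normalized"].values.to_csv(out / "normalized.tsv", sep="\t", na_rep="")
    res["de_table"].to_csv(out / "de_results.tsv", sep="\t", index=False)
    prof_rows = [
        {"feature": p.feature, **{g: p.levels[g] for g in ("WTV", "WTC", "KOV", "KOC")},
         **{f"dir_{c}": (p.direction(c) or "") for c in
            ("wt_axis", "ko_axis", "villi", "crypts")}}
        for p in res["mirna_profiles"].values()
    ]
    pd.DataFrame(prof_rows).to_csv(out / "gradient_profiles.tsv", sep="\t", index=False)
    res["gradient_changes"].to_csv(out / "gradient_changes.tsv", sep="\t", index=False)
    res["pca_coords"].to_csv(out / "pca_coordinates.tsv", sep="\t")
    write_selection(res["purity"], out / "fraction_purity.tsv")
    candidates = select_candidate_spots(bundle.spot_records, cfg.candidate_fold_cutoff)
    picked = select_candidate_spots(bundle.spot_records, cfg.selected_fold_cutoff)
    from .dige import write_spot_table

    write_spot_table(candidates, out / "spot_candidates.tsv")
    res["integration"].to_frame().to_csv(out / "integration.tsv", sep="\t", index=False)

    qualifying = res["integration"].qualifying
    summary = {
        "n_assays": int(bundle.cp_matrix.cp.shape[0]),
        "n_samples": int(bundle.cp_matrix.cp.shape[1]),
        "common_assays": len(res["normalized"].common_assays),
        "n_selected_feature_comparisons": int(res["de_table"]["selected"].sum()),
        "purest_villus_fraction": str(res["purity"].villus_fraction),
        "purest_crypt_fraction": str(res["purity"].crypt_fraction),
        "n_candidate_spots": len(candidates),
        "n_selected_spots": len(picked),
        "n_links_evaluated": len(res["integration"].verdicts),
        "n_qualifying_pairs": len(qualifying),
        "qualifying_pairs": sorted((v.mirna, v.gene) for v in qualifying),
    }
    if bundle.ground_truth.de_mirnas:
        summary["planted_de_recall"] = planted_de_recall(
            bundle.ground_truth, res["de_table"])
        summary["null_type_i_rate"] = null_type_i_rate(
            bundle.ground_truth, res["de_table"], alpha=cfg.alpha)
    if bundle.ground_truth.true_pairs:
        prec, rec = pair_recovery(bundle.ground_truth, qualifying)
        summary["pair_precision"], summary["pair_recall"] = prec, rec

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(cfg).items() if k != "simulate"},
            "simulate": cfg.simulate.to_dict() if cfg.simulate else None,
        },
        "input_hashes": input_hashes,
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
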