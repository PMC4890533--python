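"""Ground-truth-annotated synthetic input bundles.

No raw panel or gel data accompany the study design this pipeline targets,
so every downstream stage is exercised on simulated inputs with planted,
recoverable structure:

* a qPCR panel Cp matrix over the four groups (WTV/WTC/KOV/KOC) with
  replicate noise on the cycle scale, detectability dropout and a
  negative-control level;
* an 11-fraction marker series with monotone villus/crypt marker trends;
* a DeCyder-style signed spot-fold table for the proteins;
* a miRNA → gene target map mixing planted true links with random decoys.

A chosen fraction of miRNAs carries a planted crypt-villus effect per
genotype, applied as a Cp shift of equal magnitude and opposite sign
(log2 expression and cycles cancel one for one).  Each planted miRNA-protein
pair gives the protein the strictly opposite direction pattern, so the
pair is inversely concordant by construction before noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import COMPARISONS, COMPARISON_ORDER, GROUPS
from .dige import SpotRecord, signed_fold_from_levels, write_spot_table
from .errors import ConfigurationError
from .fraction_purity import MarkerTable
from .integration import TargetMap, build_target_map
from .qpcr import CpMatrix, write_cp_matrix

PREDICTION_SOURCES = ("source1", "source2", "source3")

#: (wt axis, ko axis) planted direction patterns, as log2-effect signs;
#: every pattern has at least one nonzero axis
_DE_PATTERNS = [(1, -1), (-1, 1), (1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)]


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the study's panel design.

    Four groups with 4 replicates each, ~200 assayed miRNAs, a 2-cycle
    (4-fold) planted axis effect against 0.5 cycles of replicate noise,
    negative controls at 40 cycles, and an 11-fraction marker series.
    """

    n_mirna: int = 200
    n_protein: int = 25
    n_replicates_per_group: int = 4
    frac_de: float = 0.25
    log2_effect: float = 2.0
    cp_noise_sd: float = 0.5
    baseline_cp_range: tuple[float, float] = (24.0, 30.0)
    dropout_cp_threshold: float = 37.0
    neg_control_cp: float = 40.0
    n_planted_pairs: int = 10
    decoy_target_rate: float = 0.05
    n_fractions: int = 11
    marker_gradient_slope: float = 1.0
    marker_noise_sd: float = 0.25
    spot_log2_noise_sd: float = 0.25
    signal_anchor: float = 32768.0   # linear signal of the panel-average assay
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_mirna", "n_protein", "n_replicates_per_group",
                     "n_planted_pairs", "n_fractions"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ConfigurationError("frac_de must lie in [0, 1]")
        if not self.cp_noise_sd > 0:
            raise ConfigurationError("cp_noise_sd must be positive")
        lo, hi = self.baseline_cp_range
        if not (0 < lo <= hi):
            raise ConfigurationError("baseline_cp_range must be a positive interval")
        if self.dropout_cp_threshold <= hi:
            raise ConfigurationError(
                "dropout_cp_threshold must exceed the baseline Cp range"
            )
        if not (0.0 <= self.decoy_target_rate <= 1.0):
            raise ConfigurationError("decoy_target_rate must lie in [0, 1]")
        if self.n_fractions < 2:
            raise ConfigurationError("n_fractions must be >= 2")
        if self.signal_anchor <= 0:
            raise ConfigurationError("signal_anchor must be positive")
        n_de = round(self.frac_de * self.n_mirna)
        if self.n_planted_pairs > max(n_de, 0) and self.frac_de > 0:
            if self.n_planted_pairs > n_de:
                raise ConfigurationError(
                    "n_planted_pairs cannot exceed the number of planted DE miRNAs"
                )
        if self.frac_de == 0 and self.n_planted_pairs > 0:
            # no DE miRNAs to pair with: pairs degenerate to none
            pass
        if self.n_planted_pairs > self.n_protein:
            raise ConfigurationError("n_planted_pairs cannot exceed n_protein")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "baseline_cp_range" in d:
            d = {**d, "baseline_cp_range": tuple(d["baseline_cp_range"])}
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_cp_range"] = list(self.baseline_cp_range)
        return d


@dataclass
class GroundTruth:
    """What was planted: DE miRNAs with true directions, true pairs, purity."""

    de_mirnas: dict[str, dict[str, str]]     # id -> comparison -> direction
    true_pairs: set[tuple[str, str]]          # (miRNA id, gene symbol)
    fraction_purity: list[float]              # per-fraction villus proportion

    def to_dict(self) -> dict:
        return {
            "de_mirnas": self.de_mirnas,
            "true_pairs": sorted(list(p) for p in self.true_pairs),
            "fraction_purity": self.fraction_purity,
        }


@dataclass
class Bundle:
    config: SimConfig
    cp_matrix: CpMatrix
    marker_table: MarkerTable
    spot_records: list[SpotRecord]
    target_map: TargetMap
    ground_truth: GroundTruth


def _direction_label(sign: int) -> str:
    return {1: "up", -1: "down", 0: "same"}[int(np.sign(sign))]


def _true_directions(wt_dir: int, ko_dir: int) -> dict[str, str]:
    """Per-comparison true directions implied by per-genotype axis signs.

    Villus levels are the shared baseline, so the villi comparison is
    always flat and the crypts comparison moves by (ko − wt).
    """
    return {
        "wt_axis": _direction_label(wt_dir),
        "ko_axis": _direction_label(ko_dir),
        "villi": "same",
        "crypts": _direction_label(ko_dir - wt_dir),
    }


def _sample_ids(config: SimConfig) -> list[str]:
    return [f"{g}_{r + 1}" for g in GROUPS
            for r in range(config.n_replicates_per_group)]


def generate_fraction_series(config: SimConfig, rng: np.random.Generator | None = None) -> MarkerTable:
    """Monotone marker trends over the isolation fractions.

    Villus markers (PepT1, Muc2) decay by ``marker_gradient_slope`` log2
    units per fraction from fraction 1; the crypt marker (Lgr5) rises at
    the same rate.  Multiplicative log-normal noise is applied after the
    trend.
    """
    if config.n_fractions < 2:
        raise ConfigurationError("n_fractions must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = np.arange(config.n_fractions, dtype=float)
    slope = config.marker_gradient_slope
    log2 = {
        "PepT1": 4.0 - slope * f,
        "Muc2": 4.0 - slope * f,
        "Lgr5": -1.0 + slope * f,
    }
    noise = rng.normal(0.0, config.marker_noise_sd, size=(config.n_fractions, 3))
    expr = pd.DataFrame(
        {m: np.exp2(v) for m, v in log2.items()},
        index=pd.RangeIndex(1, config.n_fractions + 1, name="fraction"),
    )
    expr = expr * np.exp2(noise)
    return MarkerTable(expression=expr,
                       roles={"PepT1": "villus", "Muc2": "villus", "Lgr5": "crypt"})


def generate_bundle(config: SimConfig) -> Bundle:
    """Generate one fully annotated input bundle (deterministic in seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    mirna_ids = [f"sim-miR-{i + 1:03d}" for i in range(config.n_mirna)]
    gene_ids = [f"Simg{i + 1:02d}" for i in range(config.n_protein)]

    # --- planted miRNA effects ------------------------------------------
    n_de = round(config.frac_de * config.n_mirna)
    de_idx = rng.choice(config.n_mirna, size=n_de, replace=False) if n_de else np.array([], int)
    axis_sign = np.zeros((config.n_mirna, 2), dtype=int)  # columns: wt, ko
    if n_de:
        patterns = rng.integers(0, len(_DE_PATTERNS), size=n_de)
        for row, pat in zip(de_idx, patterns):
            axis_sign[row] = _DE_PATTERNS[pat]
    effect = config.log2_effect if config.frac_de > 0 else 0.0
    de_mirnas = {
        mirna_ids[i]: _true_directions(*axis_sign[i]) for i in sorted(de_idx)
    }

    # --- Cp matrix -------------------------------------------------------
    lo, hi = config.baseline_cp_range
    baseline = rng.uniform(lo, hi, size=config.n_mirna)
    # true Cp per group: a positive log2 expression effect lowers Cp
    true_cp = {
        "WTV": baseline,
        "WTC": baseline - effect * axis_sign[:, 0],
        "KOV": baseline,
        "KOC": baseline - effect * axis_sign[:, 1],
    }
    samples = _sample_ids(config)
    cp = np.empty((config.n_mirna, len(samples)))
    for j, s in enumerate(samples):
        g = s.rsplit("_", 1)[0]
        cp[:, j] = true_cp[g] + rng.normal(0.0, config.cp_noise_sd, config.n_mirna)
    cp[cp > config.dropout_cp_threshold] = np.nan  # undetected
    cp_df = pd.DataFrame(cp, index=mirna_ids, columns=samples)
    groups = pd.Series({s: s.rsplit("_", 1)[0] for s in samples}, name="group")
    cp_matrix = CpMatrix(
        cp=cp_df,
        negative_control=pd.Series(config.neg_control_cp, index=mirna_ids),
        groups=groups,
    )

    # --- proteins and spot folds ----------------------------------------
    protein_sign = np.zeros((config.n_protein, 2), dtype=int)
    true_pairs: set[tuple[str, str]] = set()
    n_pairs = min(config.n_planted_pairs, n_de, config.n_protein)
    if n_pairs:
        paired_mirna = rng.choice(sorted(de_idx), size=n_pairs, replace=False)
        paired_protein = rng.choice(config.n_protein, size=n_pairs, replace=False)
        for mi, pi in zip(paired_mirna, paired_protein):
            protein_sign[pi] = -axis_sign[mi]          # strictly opposite
            true_pairs.add((mirna_ids[mi], gene_ids[pi]))

    spot_records: list[SpotRecord] = []
    protein_log2 = {
        "WTV": np.zeros(config.n_protein),
        "WTC": effect * protein_sign[:, 0],
        "KOV": np.zeros(config.n_protein),
        "KOC": effect * protein_sign[:, 1],
    }
    spot_no = 1000
    for label in COMPARISON_ORDER:
        first, second = COMPARISONS[label]
        diff = protein_log2[second] - protein_log2[first]
        noisy = diff + rng.normal(0.0, config.spot_log2_noise_sd, config.n_protein)
        for i, gene in enumerate(gene_ids):
            ratio = float(np.exp2(noisy[i]))
            fold = signed_fold_from_levels(1.0, ratio)
            spot_records.append(
                SpotRecord(
                    spot_id=str(spot_no + i),
                    comparison=(first, second),
                    fold=fold,
                    gene=gene,
                ).with_trend()
            )
        spot_no += 1000

    # --- target map: planted links + decoys ------------------------------
    per_source: dict[str, list[tuple[str, str]]] = {s: [] for s in PREDICTION_SOURCES}
    all_links = set(true_pairs)
    n_decoys = round(config.decoy_target_rate * config.n_mirna)
    attempts = 0
    while len(all_links) < len(true_pairs) + n_decoys and attempts < 50 * n_decoys:
        attempts += 1
        mi = int(rng.integers(config.n_mirna))
        pi = int(rng.integers(config.n_protein))
        link = (mirna_ids[mi], gene_ids[pi])
        if link not in all_links:
            all_links.add(link)
    for link in sorted(all_links):
        k = int(rng.integers(1, len(PREDICTION_SOURCES) + 1))
        chosen = rng.choice(len(PREDICTION_SOURCES), size=k, replace=False)
        for c in chosen:
            per_source[PREDICTION_SOURCES[c]].append(link)
    per_source = {s: links for s, links in per_source.items() if links}
    target_map = build_target_map(per_source or {"source1": sorted(all_links)})

    # --- fractions --------------------------------------------------------
    marker_table = generate_fraction_series(config, rng)
    purity = list(np.linspace(1.0, 0.0, config.n_fractions))

    truth = GroundTruth(
        de_mirnas=de_mirnas, true_pairs=true_pairs, fraction_purity=purity
    )
    return Bundle(
        config=config, cp_matrix=cp_matrix, marker_table=marker_table,
        spot_records=spot_records, target_map=target_map, ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# Serialization

def write_bundle(bundle: Bundle, outdir) -> dict:
    """Write the bundle as TSVs plus a JSON ground-truth manifest.

    Returns the manifest dict (also written to ``ground_truth.json``).
    """
    from .integration import write_target_map

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_cp_matrix(bundle.cp_matrix, out / "cp_matrix.tsv", out / "sample_groups.tsv")
    bundle.marker_table.expression.to_csv(out / "markers.tsv", sep="\t")
    write_spot_table(bundle.spot_records, out / "spots.tsv")
    write_target_map(bundle.target_map, out / "target_map.tsv")
    manifest = {
        "config": bundle.config.to_dict(),
        "seed": bundle.config.seed,
        "ground_truth": bundle.ground_truth.to_dict(),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Recovery metrics against the planted truth

def planted_de_recall(truth: GroundTruth, de_table: pd.DataFrame) -> float:
    """Fraction of planted miRNAs selected where their true effect lies.

    A planted miRNA counts as recovered when it is selected in at least
    one comparison whose true direction is not "same".
    """
    if not truth.de_mirnas:
        return float("nan")
    sel = de_table[de_table["selected"]]
    selected = set(zip(sel["feature"], sel["comparison"]))
    hits = 0
    for mirna, dirs in truth.de_mirnas.items():
        if any((mirna, comp) in selected for comp, d in dirs.items() if d != "same"):
            hits += 1
    return hits / len(truth.de_mirnas)


def null_type_i_rate(truth: GroundTruth, de_table: pd.DataFrame,
                     alpha: float = 0.05) -> float:
    """Fraction of null (feature, comparison) tests with p below alpha."""
    de_ids = set(truth.de_mirnas)
    null = de_table[~de_table["feature"].isin(de_ids) & de_table["p_value"].notna()]
    if null.empty:
        return float("nan")
    return float((null["p_value"] < alpha).mean())


def pair_recovery(truth: GroundTruth, qualifying: list) -> tuple[float, float]:
    """(precision, recall) of qualifying links against the planted pairs."""
    found = {(v.mirna, v.gene) for v in qualifying}
    if not found:
        return (float("nan"), 0.0 if truth.true_pairs else float("nan"))
    tp = len(found & truth.true_pairs)
    precision = tp / len(found)
    recall = tp / len(truth.true_pairs) if truth.true_pairs else float("nan")
    return (precision, recall)
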