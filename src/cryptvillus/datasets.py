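"""Bundled reference tables from the PepT1-knockout crypt-villus study.

The raw panel and gel data behind the study were never deposited, but the
identified-spot tables and the four validated miRNA-protein pairs were
published in full.  They are shipped here as small TSVs and exposed as
DataFrames / :class:`~cryptvillus.differential.GradientProfile` objects,
both as worked examples and as fixtures locking the DIGE sign convention.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import COMPARISON_ORDER
from .differential import GradientProfile
from .dige import records_from_frame
from .integration import TargetMap, build_target_map, read_target_map

#: comparison label -> bundled spot-table resource
_SPOT_FILES = {
    "wt_axis": "reference_spots_wt_axis.tsv",
    "ko_axis": "reference_spots_ko_axis.tsv",
    "villi": "reference_spots_villi.tsv",
    "crypts": "reference_spots_crypts.tsv",
}


def _resource(name: str):
    return resources.files("cryptvillus.data").joinpath(name)


def load_reference_spot_table(comparison: str) -> pd.DataFrame:
    """Identified DIGE spots for one of the four comparisons.

    Columns include the signed average fold change and the published
    overall-trend call (relative to the second-listed condition).
    """
    if comparison not in _SPOT_FILES:
        raise KeyError(f"comparison must be one of {sorted(_SPOT_FILES)}")
    with resources.as_file(_resource(_SPOT_FILES[comparison])) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"spot_id": str})


def load_reference_spot_records(comparison: str):
    return records_from_frame(load_reference_spot_table(comparison))


def load_reference_pairs() -> pd.DataFrame:
    """The four validated pairs with four-group levels and comparability."""
    with resources.as_file(_resource("reference_pairs.tsv")) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"spot_id": str})


def reference_profiles(tau: float = 1.45):
    """(miRNA profiles, protein profiles) for the four validated pairs."""
    df = load_reference_pairs()
    mirna, protein = {}, {}
    for _, row in df.iterrows():
        protein[row["gene"]] = GradientProfile(
            feature=row["gene"],
            levels={g: float(row[f"p_{g}"]) for g in ("WTV", "WTC", "KOV", "KOC")},
            comparable=frozenset(row["protein_comparable"].split(",")),
            tau=tau,
        )
        mirna[row["mirna"]] = GradientProfile(
            feature=row["mirna"],
            levels={g: float(row[f"m_{g}"]) for g in ("WTV", "WTC", "KOV", "KOC")},
            comparable=frozenset(row["mirna_comparable"].split(",")),
            tau=tau,
        )
    return mirna, protein


def load_reference_target_map() -> TargetMap:
    with resources.as_file(_resource("reference_target_map.tsv")) as path:
        return read_target_map(path)


def reference_case_with_decoys(tau: float = 1.45):
    """The four real links plus six synthetic decoy links.

    The decoy miRNAs/proteins are constructed (synthetic, not published)
    to be either concordant with or flat against their linked partner, so
    the inverse-expression filter must reject all six while keeping the
    four real pairs.  Returns (mirna_profiles, protein_profiles,
    target_map).
    """
    mirna, protein = reference_profiles(tau)
    axis = frozenset({"wt_axis", "ko_axis"})
    full = frozenset(COMPARISON_ORDER)

    def prof(name, levels, comparable):
        return GradientProfile(
            feature=name,
            levels=dict(zip(("WTV", "WTC", "KOV", "KOC"), levels)),
            comparable=comparable, tau=tau,
        )

    # decoy miRNAs tracking or ignoring a real protein's gradient
    mirna["decoy-miR-1"] = prof("decoy-miR-1", (1.0, 2.6, 1.0, 2.6), full)   # mimics Gyk
    mirna["decoy-miR-2"] = prof("decoy-miR-2", (1.0, 1.0, 1.0, 1.0), full)   # flat
    mirna["decoy-miR-3"] = prof("decoy-miR-3", (1.0, 1.2, 1.0, 1.1), full)   # near-flat
    # decoy proteins tracking or ignoring a real miRNA's gradient
    protein["Decoyg1"] = prof("Decoyg1", (1.0, 0.3, 1.0, 0.3), axis)         # mimics miR-33-5p
    protein["Decoyg2"] = prof("Decoyg2", (1.0, 1.0, 1.0, 1.0), full)         # flat
    protein["Decoyg3"] = prof("Decoyg3", (1.0, 2.2, 1.0, 1.0), axis)         # mimics miR-200c-5p

    links = [(m, g) for m, g in (
        ("miR-33-5p", "Gyk"), ("miR-221-3p", "Serpinb1a"),
        ("miR-200c-5p", "Rpsa"), ("miR-212-3p", "Actb"),
        ("decoy-miR-1", "Gyk"), ("decoy-miR-2", "Rpsa"),
        ("decoy-miR-3", "Serpinb1a"), ("miR-33-5p", "Decoyg1"),
        ("miR-212-3p", "Decoyg2"), ("miR-200c-5p", "Decoyg3"),
    )]
    target_map = build_target_map({"predicted": links})
    return mirna, protein, target_map
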