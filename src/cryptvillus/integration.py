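"""miRNA-target inverse-expression concordance.

miRNAs repress their targets, so a genuine regulatory link should show the
miRNA and its target protein moving in *opposite* directions along the
crypt-villus axis or between genotypes.  Given per-feature four-group
gradient profiles (:class:`~cryptvillus.differential.GradientProfile`) and
a predicted target map, each linked (miRNA, protein) pair is evaluated
comparison by comparison:

* a comparison contributes only if **both** profiles are scale-comparable
  on it (DIGE-derived protein levels are often normalized per genotype and
  support only the two axis comparisons);
* the relation per comparison is ``opposite`` (strictly opposed non-flat
  directions), ``same`` (identical non-flat directions), ``one-sided``
  (exactly one flat) or ``both-same`` (both flat);
* the pair **qualifies** iff at least one comparable comparison is
  ``opposite`` and none is ``same`` — any observed co-movement disproves
  "reverse expression".

Target maps aggregate several prediction algorithms; links carry their
source provenance and can be merged by union (default, recall-safe) or by
requiring at least k sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .design import COMPARISON_ORDER, DEFAULT_TAU
from .differential import GradientProfile
from .errors import ConfigurationError, InputError

RELATIONS = ("opposite", "same", "one-sided", "both-same")


@dataclass
class TargetMap:
    """miRNA → gene links with per-link prediction-source provenance.

    ``links`` maps miRNA id → {gene symbol → frozenset of source names}.
    """

    links: dict[str, dict[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for mirna, genes in self.links.items():
            if not genes:
                raise InputError(f"empty gene set for {mirna}")
            for gene, sources in genes.items():
                if not gene:
                    raise InputError(f"empty gene symbol under {mirna}")
                if not sources:
                    raise InputError(f"link {mirna}->{gene} has no provenance")

    def __contains__(self, pair: tuple[str, str]) -> bool:
        mirna, gene = pair
        return gene in self.links.get(mirna, {})

    def pairs(self) -> list[tuple[str, str]]:
        return [(m, g) for m, genes in self.links.items() for g in sorted(genes)]

    def sources(self, mirna: str, gene: str) -> frozenset[str]:
        return self.links[mirna][gene]


def build_target_map(
    sources: Mapping[str, Iterable[tuple[str, str]]],
    combine_rule: str = "union",
) -> TargetMap:
    """Merge per-algorithm link lists into one provenance-carrying map.

    ``sources`` maps source name → iterable of (miRNA, gene) links.
    ``combine_rule`` is ``"union"`` (keep every link, recall-safe) or
    ``"intersection-of-k"`` for integer k (keep links predicted by at
    least k sources).
    """
    if not sources:
        raise ConfigurationError("at least one prediction source table is required")
    tally: dict[str, dict[str, set[str]]] = {}
    for name, links in sources.items():
        for mirna, gene in links:
            tally.setdefault(mirna, {}).setdefault(gene, set()).add(name)
    if combine_rule == "union":
        min_sources = 1
    elif combine_rule.startswith("intersection-of-"):
        try:
            min_sources = int(combine_rule.rsplit("-", 1)[1])
        except ValueError:
            raise ConfigurationError(f"unknown combine rule: {combine_rule!r}")
        if min_sources < 1:
            raise ConfigurationError(f"combine rule needs k >= 1: {combine_rule!r}")
    else:
        raise ConfigurationError(f"unknown combine rule: {combine_rule!r}")
    links: dict[str, dict[str, frozenset[str]]] = {}
    for mirna, genes in tally.items():
        kept = {g: frozenset(s) for g, s in genes.items() if len(s) >= min_sources}
        if kept:
            links[mirna] = kept
    return TargetMap(links=links)


@dataclass
class ComparisonDetail:
    comparison: str
    mirna_direction: str | None
    protein_direction: str | None
    comparable: bool
    relation: str | None


@dataclass
class ConcordanceVerdict:
    mirna: str
    gene: str
    details: list[ComparisonDetail]
    verdict: str            # "qualifies" | "rejected"
    reason: str

    @property
    def qualifies(self) -> bool:
        return self.verdict == "qualifies"


def relation_of(mirna_dir: str, protein_dir: str) -> str:
    """Relation between two direction calls on one comparable comparison."""
    if mirna_dir == "same" and protein_dir == "same":
        return "both-same"
    if mirna_dir == "same" or protein_dir == "same":
        return "one-sided"
    return "opposite" if mirna_dir != protein_dir else "same"


def inverse_concordance(
    mirna: GradientProfile,
    protein: GradientProfile,
    target_map: TargetMap | None = None,
    tau: float = DEFAULT_TAU,
) -> ConcordanceVerdict:
    """Evaluate one miRNA-protein link for reverse expression.

    Directions are recomputed from the profiles' levels at ``tau`` over
    the comparisons where both profiles are scale-comparable.  If a target
    map is supplied the link must be present in it.
    """
    if target_map is not None and (mirna.feature, protein.feature) not in target_map:
        raise InputError(
            f"({mirna.feature}, {protein.feature}) is not a link in the target map"
        )
    m = GradientProfile(mirna.feature, mirna.levels, mirna.comparable, tau)
    p = GradientProfile(protein.feature, protein.levels, protein.comparable, tau)
    details: list[ComparisonDetail] = []
    opposite: list[str] = []
    same: list[str] = []
    any_comparable = False
    for comp in COMPARISON_ORDER:
        md, pd_ = m.direction(comp), p.direction(comp)
        comparable = md is not None and pd_ is not None
        rel = relation_of(md, pd_) if comparable else None
        details.append(ComparisonDetail(comp, md, pd_, comparable, rel))
        if comparable:
            any_comparable = True
            if rel == "opposite":
                opposite.append(comp)
            elif rel == "same":
                same.append(comp)
    if not any_comparable:
        verdict, reason = "rejected", "incomparable scales"
    elif same:
        verdict = "rejected"
        reason = f"concordant direction in {', '.join(same)}"
    elif opposite:
        verdict = "qualifies"
        reason = f"opposite in {', '.join(opposite)}"
    else:
        verdict, reason = "rejected", "no opposite comparison"
    return ConcordanceVerdict(
        mirna=mirna.feature, gene=protein.feature,
        details=details, verdict=verdict, reason=reason,
    )


@dataclass
class IntegrationReport:
    verdicts: list[ConcordanceVerdict]
    skipped: list[tuple[str, str, str]]  # (miRNA, gene, why)

    @property
    def qualifying(self) -> list[ConcordanceVerdict]:
        return [v for v in self.verdicts if v.qualifies]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-link table (one row per evaluated link)."""
        rows = []
        for v in self.verdicts:
            row = {"mirna": v.mirna, "gene": v.gene,
                   "verdict": v.verdict, "reason": v.reason}
            for d in v.details:
                row[f"{d.comparison}_relation"] = d.relation or ""
            rows.append(row)
        return pd.DataFrame(rows)


def integrate(
    mirna_profiles: Mapping[str, GradientProfile],
    protein_profiles: Mapping[str, GradientProfile],
    target_map: TargetMap,
    tau: float = DEFAULT_TAU,
) -> IntegrationReport:
    """Evaluate every target-map link with both profiles present.

    Links whose miRNA or protein has no measured profile are skipped and
    logged, not treated as errors.
    """
    verdicts: list[ConcordanceVerdict] = []
    skipped: list[tuple[str, str, str]] = []
    for mirna_id, gene in target_map.pairs():
        if mirna_id not in mirna_profiles:
            skipped.append((mirna_id, gene, "no miRNA profile"))
            continue
        if gene not in protein_profiles:
            skipped.append((mirna_id, gene, "no protein profile"))
            continue
        verdicts.append(
            inverse_concordance(
                mirna_profiles[mirna_id], protein_profiles[gene],
                target_map=target_map, tau=tau,
            )
        )
    return IntegrationReport(verdicts=verdicts, skipped=skipped)


# ---------------------------------------------------------------------------
# TSV / GMT-like I/O

def read_target_map(path, combine_rule: str = "union") -> TargetMap:
    """Read a target map TSV with columns miRNA, gene, sources.

    ``sources`` is a comma-separated list of prediction-source names.  A
    two-column file is accepted and assigned the provenance "unspecified".
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputError("target map needs at least miRNA and gene columns")
    per_source: dict[str, list[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        mirna, gene = row.iloc[0], row.iloc[1]
        srcs = row.iloc[2] if df.shape[1] > 2 and isinstance(row.iloc[2], str) else "unspecified"
        for s in srcs.split(","):
            per_source.setdefault(s.strip(), []).append((mirna, gene))
    return build_target_map(per_source, combine_rule=combine_rule)


def write_target_map(target_map: TargetMap, path) -> None:
    rows = [
        {"mirna": m, "gene": g, "sources": ",".join(sorted(target_map.sources(m, g)))}
        for m, g in target_map.pairs()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
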