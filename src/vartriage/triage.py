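"""Variant triage: ligandability consensus and the four-criterion
drug-repurposing feasibility report (DRARDT).

A missense variant is worth pursuing with a small molecule only if the
mutant protein exists (no transcript decay), the mutated site sits in a
well-defined structural region, and the site is ligandable.  This module
takes externally predicted per-variant scores (pathogenicity from two
predictors, conservation grade, disorder propensity, relative solvent
accessibility, and up to three independent folding-stability ΔΔG values)
and applies the fixed decision thresholds:

* pathogenicity: MutPred2-style score ≥ 0.80 and E-SNPs&GO-style p ≥ 0.50
  each call "pathogenic"; agreement is required for a consensus;
* disorder: score ≥ 0.50 puts the site in an intrinsically disordered
  region;
* exposure: RSA > 20% is solvent-exposed;
* stability: any ΔΔG ≤ −1.5 kcal/mol calls the variant highly
  destabilizing ("over_threshold").

The ligandability gate is minimal: a site is ligandable iff it is
solvent-exposed and not highly destabilizing.  Pathogenicity,
conservation and disorder are reported as context.

The DRARDT report combines four target-level criteria: literature volume,
NMD percentage, structural definition at mutation sites, and interactome
size, each flagged High / Medium / Low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .context import SiteDefinitionReport
from .nmd import NmdSummary
from .structmodel import VariantRecord

__all__ = [
    "PredictorScoreRecord",
    "TriageCall",
    "DrardtReport",
    "call_pathogenicity",
    "call_disorder",
    "call_destabilizing",
    "call_ligandable",
    "flag_literature",
    "flag_interactome",
    "drardt_assess",
    "MUTPRED_THRESHOLD",
    "ESNPGO_THRESHOLD",
    "DISORDER_CUTOFF",
    "RSA_THRESHOLD",
    "DDG_CUTOFF",
]

MUTPRED_THRESHOLD = 0.80      # conservative threshold reducing false positives
MUTPRED_WEAK_THRESHOLD = 0.50  # above this the tool leans pathogenic
ESNPGO_THRESHOLD = 0.50
DISORDER_CUTOFF = 0.50
RSA_THRESHOLD = 20.0          # percent
DDG_CUTOFF = -1.5             # kcal/mol; at or below = highly destabilizing

Flag = Literal["High", "Medium", "Low"]


@dataclass
class PredictorScoreRecord:
    """One variant's bundle of external predictor outputs.

    ``ddg`` holds up to three independent stability predictions in
    kcal/mol (negative = destabilizing), in a fixed tool order; missing
    values are None.  ``rsa`` may be supplied from an external run or
    computed internally from a structure.
    """

    variant: VariantRecord
    mutpred: float | None = None
    esnpgo: float | None = None
    consurf_grade: int | None = None
    disorder: float | None = None
    rsa: float | None = None
    ddg: tuple[float | None, float | None, float | None] = (None, None, None)

    def __post_init__(self) -> None:
        for name, val in (("mutpred", self.mutpred), ("esnpgo", self.esnpgo),
                          ("disorder", self.disorder)):
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"{self.variant.label}: {name}={val} outside [0,1]")
        if self.consurf_grade is not None and not 1 <= self.consurf_grade <= 9:
            raise ValueError(f"{self.variant.label}: conservation grade outside 1-9")
        if self.rsa is not None and self.rsa < 0:
            raise ValueError(f"{self.variant.label}: negative RSA")


@dataclass
class TriageCall:
    variant: VariantRecord
    pathogenicity_call: str
    disorder_call: str
    exposure_call: str
    stability_call: str
    ligandable: bool
    rationale: dict[str, str] = field(default_factory=dict)


@dataclass
class DrardtReport:
    """Four-criterion feasibility report for one target."""

    literature_flag: Flag | None
    nmd_flag: Flag | None
    structure_flag: Flag | None
    interactome_flag: Flag | None
    detail: dict[str, object] = field(default_factory=dict)

    NOT_ASSESSED = "not assessed"

    def flags(self) -> dict[str, str]:
        return {
            "literature": self.literature_flag or self.NOT_ASSESSED,
            "nmd": self.nmd_flag or self.NOT_ASSESSED,
            "structure": self.structure_flag or self.NOT_ASSESSED,
            "interactome": self.interactome_flag or self.NOT_ASSESSED,
        }

    def to_json_dict(self) -> dict:
        out: dict = {"flags": self.flags()}
        out["detail"] = {k: v for k, v in self.detail.items()}
        return out

    def to_text(self) -> str:
        lines = ["Drug-repurposing feasibility assessment"]
        for crit, flag in self.flags().items():
            lines.append(f"  {crit:12s} {flag}")
        return "\n".join(lines)


def call_pathogenicity(mutpred: float | None, esnpgo: float | None,
                       ) -> Literal["pathogenic", "benign", "discordant"]:
    """Consensus pathogenicity from two independent predictor scores.

    Each tool casts a vote (MutPred2-style: pathogenic at ≥ 0.80, leaning
    pathogenic in [0.50, 0.80); E-SNPs&GO-style: pathogenic at p ≥ 0.50).
    Two pathogenic votes give "pathogenic", two clean benign votes
    "benign", anything else — including a lean against a benign call —
    is "discordant".  With a single available score the call follows that
    tool alone and is marked single-source by the caller.
    """
    if mutpred is None and esnpgo is None:
        raise ValueError("no pathogenicity score available")
    if mutpred is None:
        return "pathogenic" if esnpgo >= ESNPGO_THRESHOLD else "benign"
    if esnpgo is None:
        return "pathogenic" if mutpred >= MUTPRED_THRESHOLD else "benign"
    mp = ("pathogenic" if mutpred >= MUTPRED_THRESHOLD
          else "leaning" if mutpred >= MUTPRED_WEAK_THRESHOLD else "benign")
    es = "pathogenic" if esnpgo >= ESNPGO_THRESHOLD else "benign"
    if mp == "pathogenic" and es == "pathogenic":
        return "pathogenic"
    if mp == "benign" and es == "benign":
        return "benign"
    return "discordant"


def call_disorder(disorder_score: float,
                  cutoff: float = DISORDER_CUTOFF) -> Literal["idr", "structured"]:
    """Disorder call: score at or above the cutoff is an intrinsically
    disordered region."""
    if not 0.0 <= disorder_score <= 1.0:
        raise ValueError(f"disorder score {disorder_score} outside [0,1]")
    return "idr" if disorder_score >= cutoff else "structured"


def call_destabilizing(
    ddg: Sequence[float | None],
    cutoff: float = DDG_CUTOFF,
) -> Literal["over_threshold", "tolerated"]:
    """Stability consensus: highly destabilizing if any available ΔΔG is at
    or below the cutoff (−1.5 kcal/mol)."""
    available = [v for v in ddg if v is not None]
    if not available:
        raise ValueError("no ΔΔG value available for a stability call")
    return "over_threshold" if any(v <= cutoff for v in available) else "tolerated"


def call_ligandable(record: PredictorScoreRecord,
                    rsa_threshold: float = RSA_THRESHOLD,
                    ddg_cutoff: float = DDG_CUTOFF) -> TriageCall:
    """Full per-variant triage.

    Ligandable ⟺ solvent-exposed and not highly destabilizing.  The other
    calls (pathogenicity consensus, disorder, conservation) are reported
    as context but do not gate.
    """
    from .sasa import classify_exposure

    if record.rsa is None:
        raise ValueError(f"{record.variant.label}: RSA required for a triage call")
    pathogenicity = call_pathogenicity(record.mutpred, record.esnpgo)
    disorder = (call_disorder(record.disorder)
                if record.disorder is not None else "unknown")
    exposure = classify_exposure(record.rsa, rsa_threshold)
    stability = call_destabilizing(record.ddg, ddg_cutoff)
    ligandable = (exposure == "exposed") and (stability == "tolerated")

    single_source = (record.mutpred is None) != (record.esnpgo is None)
    rationale = {
        "pathogenicity": (
            f"mutpred={record.mutpred}, esnpgo={record.esnpgo} -> {pathogenicity}"
            + (" [single-source]" if single_source else "")),
        "disorder": f"score={record.disorder} (cutoff {DISORDER_CUTOFF}) -> {disorder}",
        "exposure": f"rsa={record.rsa}% (threshold {rsa_threshold}%) -> {exposure}",
        "stability": f"ddg={record.ddg} (cutoff {ddg_cutoff}) -> {stability}",
        "gate": "ligandable iff exposed and not over-threshold destabilizing",
    }
    return TriageCall(
        variant=record.variant,
        pathogenicity_call=pathogenicity,
        disorder_call=disorder,
        exposure_call=exposure,
        stability_call=stability,
        ligandable=ligandable,
        rationale=rationale,
    )


def flag_literature(publication_count: int,
                    thresholds: tuple[int, int] = (100, 500)) -> Flag:
    """Literature-volume flag from a publication count.

    Half-open bands: below the first threshold Low, below the second
    Medium, else High.  Default thresholds are provisional and
    configuration-exposed.
    """
    if publication_count < 0:
        raise ValueError("negative publication count")
    low_bound, high_bound = thresholds
    if publication_count < low_bound:
        return "Low"
    if publication_count < high_bound:
        return "Medium"
    return "High"


def flag_interactome(n_interactors: int, n_pathways: int) -> Flag:
    """Interactome flag: fewer than 3 interactors is Low (Medium when the
    protein sits in at least one annotated pathway); more than 3 is High;
    exactly 3 is Medium."""
    if n_interactors < 0 or n_pathways < 0:
        raise ValueError("negative count")
    if n_interactors > 3:
        return "High"
    if n_interactors == 3:
        return "Medium"
    return "Medium" if n_pathways >= 1 else "Low"


_PESSIMISM = {"Low": 0, "Medium": 1, "High": 2}


def _structure_flag(site_report: SiteDefinitionReport) -> Flag:
    """Majority label over per-site labels; ties break pessimistic."""
    labels = [lab.value for lab in site_report.site_labels.values()]
    if not labels:
        raise ValueError("no classified sites")
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == top]
    return min(winners, key=lambda lab: _PESSIMISM[lab])  # type: ignore[return-value]


def drardt_assess(
    publication_count: int | None = None,
    nmd: NmdSummary | None = None,
    site_report: SiteDefinitionReport | None = None,
    interactome: tuple[int, int] | None = None,
    literature_thresholds: tuple[int, int] = (100, 500),
) -> DrardtReport:
    """Compose the four-criterion feasibility report.

    Any missing criterion yields a partial report with an explicit
    "not assessed" marker rather than an error.
    """
    detail: dict[str, object] = {}

    literature_flag = None
    if publication_count is not None:
        literature_flag = flag_literature(publication_count, literature_thresholds)
        detail["literature"] = {"publications": publication_count}

    nmd_flag = None
    if nmd is not None:
        if nmd.n_confident == 0:
            detail["nmd"] = {"error": "no confident protein-level calls"}
        else:
            nmd_flag = nmd.flag
            detail["nmd"] = {
                "percentage": round(nmd.percentage, 1),
                "n_nmd": nmd.n_nmd,
                "n_confident": nmd.n_confident,
                "n_low_confidence": nmd.n_low_confidence,
            }

    structure_flag = None
    if site_report is not None and site_report.site_labels:
        structure_flag = _structure_flag(site_report)
        detail["structure"] = {
            "basis": site_report.basis,
            "per_site": {lab: d.value for lab, d in site_report.site_labels.items()},
            "census": dict(site_report.census),
            "census_size": site_report.n_census_residues,
        }

    interactome_flag = None
    if interactome is not None:
        n_int, n_path = interactome
        interactome_flag = flag_interactome(n_int, n_path)
        detail["interactome"] = {"interactors": n_int, "pathways": n_path}

    return DrardtReport(
        literature_flag=literature_flag,
        nmd_flag=nmd_flag,
        structure_flag=structure_flag,
        interactome_flag=interactome_flag,
        detail=detail,
    )
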