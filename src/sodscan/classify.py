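"""Per-variant structural-consequence classification.

Every candidate rotamer of the substituted residue is built on the fixed
backbone and scored against the local environment; the per-rotamer contact
reports are condensed into a verdict over the vocabulary

* STERIC_CLASH  -- the substitution loses (more than half of) the
                   conformational freedom the wild-type amino acid has at
                   the site: its clash-free rotamer fraction falls below a
                   set multiple of the wild type's own clash-free fraction
* LOSS_VDW      -- the best clash-free rotamer keeps less than a set
                   fraction of the wild-type side chain's van der Waals
                   contacts
* LOSS_HBOND    -- wild-type side-chain hydrogen bonds cannot be re-formed
                   by any clash-free rotamer
* NONE          -- none of the above triggers

In-frame deletions are never modelled geometrically: removing a residue
shifts everything C-terminal out of register with its stabilising
hydrogen-bond partners, so deletions get a rule-based LOSS_HBOND verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .contacts import ContactReport, ScanParams, score_rotamer
from .rotamers import (
    ChiAngles,
    Rotamer,
    RotamerLibrary,
    VariantSpec,
    enumerate_rotamers,
    grid_rotamers,
    load_default_library,
)
from .residues import chi_count
from .structure import Protomer
from .superpose import measure_chi, measure_phi_psi

__all__ = [
    "Consequence",
    "ConsequenceCall",
    "classify_variant",
    "scan_panel",
    "SEVERITY",
]


class Consequence(str, Enum):
    STERIC_CLASH = "Steric clash"
    LOSS_VDW = "Loss of van der Waals"
    LOSS_HBOND = "Loss of H-bonds"
    NONE = "None"


# severity order used by the isostericity sanity property
SEVERITY = {
    Consequence.NONE: 0,
    Consequence.LOSS_HBOND: 1,
    Consequence.LOSS_VDW: 1,
    Consequence.STERIC_CLASH: 2,
}


@dataclass
class ConsequenceCall:
    variant: VariantSpec
    labels: frozenset[Consequence]
    rule_based: bool = False
    evidence: dict = field(default_factory=dict)
    thresholds_used: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.labels:
            raise ValueError("a call must carry at least one label")
        if Consequence.NONE in self.labels and len(self.labels) > 1:
            raise ValueError("NONE is exclusive of other labels")
        if self.rule_based and not self.variant.is_deletion:
            raise ValueError("rule_based calls are reserved for deletions")

    @property
    def severity(self) -> int:
        return max(SEVERITY[l] for l in self.labels)

    def label_text(self) -> str:
        """Human-readable label set, most severe first."""
        ordered = sorted(self.labels, key=lambda l: -SEVERITY[l])
        if self.labels == {Consequence.STERIC_CLASH, Consequence.LOSS_VDW}:
            # conventional printing order for the dual verdict
            return "Loss of van der Waals, Steric clash"
        return ", ".join(l.value for l in ordered)

    def to_dict(self) -> dict:
        return {
            "variant": str(self.variant),
            "labels": sorted(l.name for l in self.labels),
            "label_text": self.label_text(),
            "rule_based": self.rule_based,
            "evidence": self.evidence,
            "thresholds_used": self.thresholds_used,
        }


def _rotamer_candidates(
    protomer: Protomer,
    variant: VariantSpec,
    library: RotamerLibrary,
    params: ScanParams,
) -> list[Rotamer]:
    if params.rotamer_mode == "grid":
        return grid_rotamers(variant.substitution, params.grid_step)
    if library.backbone_dependent:
        phi, psi = measure_phi_psi(protomer, variant.position)
        if phi is None or psi is None:
            return enumerate_rotamers(
                variant.substitution,
                RotamerLibrary(library.entries, backbone_dependent=False),
            )
        return enumerate_rotamers(variant.substitution, library, (phi, psi))
    return enumerate_rotamers(variant.substitution, library)


def classify_variant(
    protomer: Protomer,
    variant: VariantSpec,
    library: RotamerLibrary | None = None,
    params: ScanParams | None = None,
) -> ConsequenceCall:
    """Classify one substitution (or deletion) on a template protomer."""
    params = params or ScanParams()
    library = library or load_default_library()

    if variant.is_deletion:
        return ConsequenceCall(
            variant=variant,
            labels=frozenset({Consequence.LOSS_HBOND}),
            rule_based=True,
            evidence={
                "rule": "in-frame deletion shifts all C-terminal residues out of "
                "register with their stabilising hydrogen-bond partners"
            },
            thresholds_used=params.as_dict(),
        )

    template = protomer.residue(variant.position)
    try:
        wt_chi = measure_chi(template)
    except Exception:  # incomplete or degenerate template side chain
        wt_chi = None

    def candidates(aa: str) -> list[Rotamer]:
        rots = _rotamer_candidates(
            protomer, VariantSpec(variant.position, variant.wild_type, aa),
            library, params,
        )
        # the template's observed conformation is always a candidate for
        # amino acids sharing the wild type's chi structure
        if wt_chi is not None and chi_count(aa) == len(wt_chi.values):
            rots = rots + [
                Rotamer(aa, ChiAngles(wt_chi.values, aa), source="library",
                        label="wt-observed")
            ]
        return rots

    rotamers = candidates(variant.substitution)
    scored: list[tuple[Rotamer, ContactReport]] = []
    wt_report: ContactReport | None = None
    for rot in rotamers:
        var_rep, wt_rep = score_rotamer(protomer, variant, rot, params)
        scored.append((rot, var_rep))
        wt_report = wt_rep
    assert wt_report is not None

    # baseline: the wild-type amino acid rebuilt through the same machinery
    wt_identity = VariantSpec(variant.position, variant.wild_type, variant.wild_type)
    wt_scored = [
        score_rotamer(protomer, wt_identity, rot, params)[0]
        for rot in candidates(variant.wild_type)
    ]
    wt_frac_clash_free = sum(r.n_clashes == 0 for r in wt_scored) / len(wt_scored)

    clash_free = [(r, rep) for r, rep in scored if rep.n_clashes == 0]
    frac_clash_free = len(clash_free) / len(scored)
    labels: set[Consequence] = set()
    if frac_clash_free < params.clash_free_fraction * wt_frac_clash_free:
        labels.add(Consequence.STERIC_CLASH)

    if clash_free:
        best_rot, best_rep = max(
            clash_free, key=lambda t: (t[1].n_contacts, t[1].n_hbonds)
        )
    else:
        best_rot, best_rep = min(
            scored, key=lambda t: (t[1].n_clashes, t[1].worst_overlap)
        )
    if wt_report.n_contacts > 0 and (
        best_rep.n_contacts < params.f_contact * wt_report.n_contacts
    ):
        labels.add(Consequence.LOSS_VDW)
    if wt_report.n_hbonds > 0 and clash_free:
        best_hbonds = max(rep.n_hbonds for _r, rep in clash_free)
        if best_hbonds < wt_report.n_hbonds:
            labels.add(Consequence.LOSS_HBOND)

    if not labels:
        labels = {Consequence.NONE}
    return ConsequenceCall(
        variant=variant,
        labels=frozenset(labels),
        rule_based=False,
        evidence={
            "n_rotamers": len(scored),
            "rotamer_source": rotamers[0].source if rotamers else "library",
            "clash_free_fraction": round(frac_clash_free, 4),
            "wt_clash_free_fraction": round(wt_frac_clash_free, 4),
            "best_rotamer": {
                "label": best_rot.label,
                "chi": list(best_rot.chi.values),
                "n_clashes": best_rep.n_clashes,
                "n_contacts": best_rep.n_contacts,
                "n_hbonds": best_rep.n_hbonds,
                "worst_overlap": best_rep.worst_overlap,
            },
            "wild_type": {
                "n_contacts": wt_report.n_contacts,
                "n_hbonds": wt_report.n_hbonds,
                "n_clashes": wt_report.n_clashes,
            },
            "contact_retention": (
                round(best_rep.n_contacts / wt_report.n_contacts, 4)
                if wt_report.n_contacts
                else None
            ),
            "environment_residues": wt_report.environment,
        },
        thresholds_used=params.as_dict(),
    )


def scan_panel(
    protomer: Protomer,
    variants: list[VariantSpec],
    library: RotamerLibrary | None = None,
    params: ScanParams | None = None,
    expected_labels: dict[str, str] | None = None,
) -> tuple[list[ConsequenceCall], list[tuple[VariantSpec, str]], list[dict]]:
    """Classify a panel of variants, collecting per-variant errors.

    Returns (calls, errors, concordance rows); concordance rows are filled
    when ``expected_labels`` maps variant strings (e.g. "E40G") to expected
    label text.
    """
    calls: list[ConsequenceCall] = []
    errors: list[tuple[VariantSpec, str]] = []
    for variant in variants:
        try:
            calls.append(classify_variant(protomer, variant, library, params))
        except (ValueError, KeyError) as exc:
            errors.append((variant, str(exc)))
    concordance: list[dict] = []
    if expected_labels:
        for call in calls:
            key = str(call.variant)
            if key not in expected_labels:
                continue
            expected = expected_labels[key]
            got = call.label_text()
            concordance.append(
                {
                    "variant": key,
                    "expected": expected,
                    "predicted": got,
                    "concordant": _normalise(expected) == _normalise(got),
                }
            )
    return calls, errors, concordance


def _normalise(label: str) -> frozenset[str]:
    parts = [p.strip().lower() for p in label.split(",")]
    return frozenset(p for p in parts if p)
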