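"""Rule-based lambda-max assignment from tuning-site profiles.

Three of the five opsin classes can be read straight off the sequence:

* SWS1 — UV sensitivity hinges on site 86: phenylalanine keeps the pigment
  UV-sensitive at 360 nm; any other residue shifts it into the violet and
  no numeric value is assigned by rule.
* LWS — the additive "five-sites" rule over sites 164/181/261/269/292:
  base 560 nm for the ancestral S/H/Y/T/A state, with fixed negative
  shifts for each of S164A, H181Y, Y261F, T269A, A292S.
* RH1 — 27 rod-opsin sites are annotated against the literature; a numeric
  estimate (500 nm base plus registered deltas) is reported but flagged
  approximate, because no complete additive rule set exists for rods.

RH2 gets only the qualitative E122Q call here (green- vs blue-shifted
around 495 nm); its numeric lambda-max comes from the dynamics-descriptor
regression in :mod:`opsintune.spectral`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .sequences import GAP, TuningSiteProfile

__all__ = [
    "SpectralPrediction",
    "RuleShift",
    "RuleTable",
    "load_lws_rule_table",
    "load_rh1_annotations",
    "predict_sws1",
    "predict_lws_five_site",
    "report_rh1_sites",
    "classify_rh2_e122q",
]

#: Plausible lambda-max windows (nm) per class, used for range flags.
CLASS_RANGES = {
    "sws1": (355.0, 445.0),
    "sws2": (400.0, 470.0),
    "rh2": (460.0, 530.0),
    "rh1": (460.0, 530.0),
    "lws": (500.0, 575.0),
}


@dataclass
class SpectralPrediction:
    """A lambda-max call with its provenance.

    ``lambda_max`` may be None when only a qualitative call is possible
    (e.g. a violet-shifted SWS1). ``notes`` records every rule firing.
    """

    pigment_id: str
    opsin_class: str
    lambda_max: float | None
    method: str  # "rule_based" | "regression"
    chromophore: str = "A1"
    flags: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ("rule_based", "regression"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "rule_based" and not self.notes:
            raise ValueError("rule_based predictions must record rule firings")
        if self.lambda_max is not None and not (
                300.0 <= self.lambda_max <= 650.0):
            # raw regression output may legitimately leave the physical
            # window; callers flag rather than clip (see spectral module)
            if "out_of_range" not in self.flags:
                raise ValueError(
                    f"lambda_max {self.lambda_max} nm outside 300-650 nm "
                    "and not flagged out_of_range"
                )


@dataclass(frozen=True)
class RuleShift:
    site: int
    ancestral: str
    substituted: str
    delta_nm: float
    citation: str = ""


@dataclass
class RuleTable:
    """Additive shift rules for one opsin class."""

    opsin_class: str
    base_lambda: float
    shifts: list[RuleShift]

    def by_site(self) -> dict[int, RuleShift]:
        return {s.site: s for s in self.shifts}


def _read_rule_tsv(name: str) -> list[dict]:
    ref = resources.files("opsintune.data") / name
    with resources.as_file(ref) as path, open(path) as fh:
        rows = [r for r in csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t")]
    return rows


def load_lws_rule_table(path: str | Path | None = None) -> RuleTable:
    """The packaged five-sites rule table (config-overridable)."""
    if path is None:
        rows = _read_rule_tsv("lws_five_sites.tsv")
    else:
        with open(path) as fh:
            rows = list(csv.DictReader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"))
    shifts = [RuleShift(int(r["site"]), r["ancestral"], r["substituted"],
                        float(r["delta_nm"]), r.get("citation", ""))
              for r in rows]
    return RuleTable(opsin_class="lws", base_lambda=560.0, shifts=shifts)


def load_rh1_annotations() -> list[dict]:
    rows = _read_rule_tsv("rh1_site_annotations.tsv")
    for r in rows:
        r["site"] = int(r["site"])
        r["delta_nm"] = float(r["delta_nm"])
    return rows


def predict_sws1(profile: TuningSiteProfile) -> SpectralPrediction:
    """UV/violet call for an SWS1 pigment from site 86.

    F86 keeps the chromophore environment UV-sensitive (360 nm); other
    residues produce a violet-shifted pigment whose value is not assigned
    by this rule.
    """
    if 86 not in profile.residues:
        raise ValueError(f"{profile.pigment_id}: profile lacks site 86")
    res = profile.residues[86]
    if res == GAP:
        raise ValueError(f"{profile.pigment_id}: site 86 unalignable")
    if res == "F":
        return SpectralPrediction(
            pigment_id=profile.pigment_id, opsin_class="sws1",
            lambda_max=360.0, method="rule_based",
            notes=["site 86 = F: UVS, lambda_max 360 nm"],
        )
    return SpectralPrediction(
        pigment_id=profile.pigment_id, opsin_class="sws1",
        lambda_max=None, method="rule_based",
        notes=[f"site 86 = {res}: violet-shifted (non-UVS), "
               "not numerically predicted"],
    )


def predict_lws_five_site(profile: TuningSiteProfile,
                          table: RuleTable | None = None
                          ) -> SpectralPrediction:
    """Additive five-sites rule for LWS pigments.

    Starts from the 560 nm ancestral state and subtracts the registered
    shift for every substituted site. Unalignable sites are skipped and the
    prediction carries an ``incomplete`` flag; unexpected residues are
    skipped with a warning note.
    """
    table = table or load_lws_rule_table()
    by_site = table.by_site()
    missing = sorted(set(by_site) - set(profile.residues))
    if missing:
        raise ValueError(
            f"{profile.pigment_id}: profile lacks required sites {missing}")
    value = table.base_lambda
    flags: list[str] = []
    notes: list[str] = []
    for site in sorted(by_site):
        rule = by_site[site]
        res = profile.residues[site]
        if res == GAP:
            flags.append("incomplete")
            notes.append(f"site {site} unalignable; skipped")
        elif res == rule.ancestral:
            notes.append(f"site {site} = {res}: ancestral, no shift")
        elif res == rule.substituted:
            value += rule.delta_nm
            notes.append(
                f"site {site} = {res}: {rule.ancestral}{site}{res}, "
                f"{rule.delta_nm:+g} nm")
        else:
            flags.append("unknown_residue")
            notes.append(
                f"site {site} = {res}: not in rule table, skipped")
    return SpectralPrediction(
        pigment_id=profile.pigment_id, opsin_class="lws",
        lambda_max=value, method="rule_based", flags=flags, notes=notes,
    )


def report_rh1_sites(profile: TuningSiteProfile) -> dict:
    """Annotated per-site report for an RH1 pigment.

    Returns a dict with per-site residues, literature annotations for the
    recognised substitutions, and a best-effort lambda-max estimate
    (500 nm base plus registered deltas) that is always flagged
    ``approximate``: unlike the LWS five-sites rule, no printed additive
    rule set covers all 27 rod sites.
    """
    annotations = {r["site"]: r for r in load_rh1_annotations()}
    sites = []
    estimate = 500.0
    for site in sorted(profile.residues):
        res = profile.residues[site]
        entry: dict = {"site": site, "residue": res}
        ann = annotations.get(site)
        if ann and res == ann["substituted"]:
            entry["annotation"] = f"{ann['label']}, {ann['direction']}-shift"
            entry["delta_nm"] = ann["delta_nm"]
            estimate += ann["delta_nm"]
        sites.append(entry)
    report = {
        "pigment_id": profile.pigment_id,
        "sites": sites,
        "lambda_max_estimate": estimate if profile.residues else None,
        "flags": ["approximate"] if profile.residues else [],
    }
    return report


def classify_rh2_e122q(profile: TuningSiteProfile) -> str:
    """The E122Q switch of RH2 pigments.

    Glutamate at site 122 keeps the pigment green-shifted (lambda-max above
    ~495 nm); glutamine blue-shifts it below 495 nm, a swing of roughly
    15 nm on its own.
    """
    if 122 not in profile.residues:
        raise ValueError(f"{profile.pigment_id}: profile lacks site 122")
    res = profile.residues[122]
    if res == "E":
        return "green_shifted"
    if res == "Q":
        return "blue_shifted"
    raise ValueError(
        f"{profile.pigment_id}: site 122 is {res!r}, expected E or Q")
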