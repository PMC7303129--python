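"""Record-level somatic filters and classification rules.

These implement the explicit thresholds used for consensus indel calls and
deep targeted sequencing, the putative-driver rule engine on pre-annotated
variants, and the hyper/hypo-methylation call against the matched normal.
Inequality strictness follows the quoted thresholds exactly:

* indels: tumor alt fraction > 0.04; normal alt fraction < 0.02;
  tumor depth >= 8; normal depth >= 6; tumor alt reads > 3;
* targeted sequencing: tumor depth >= 30; alt reads >= 8;
* driver: variant in a configured driver-gene list AND either a deleterious
  consequence with SIFT < 0.05 or PolyPhen > 0.995 or a normalized
  deleteriousness (CADD-like) score > 0.99, or a recurrent / 3D-clustered
  hotspot;
* methylation: hyper/hypo at >= 20 percentage-point in-/decrease of beta
  relative to the matched normal (absolute-difference reading by default;
  ``relative=True`` switches to a +-20% relative change).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

#: consequences eligible for driver rule (i); scores decide deleteriousness
DELETERIOUS_CONSEQUENCES = {"stop-gain", "frameshift", "splicing", "missense"}

CONSEQUENCES = {"stop-gain", "frameshift", "splicing", "missense",
                "synonymous", "other"}


@dataclass
class FilterDecision:
    record: object
    verdict: str                       # pass | fail
    failed_rules: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.verdict == "fail") != bool(self.failed_rules):
            raise ValueError("verdict 'fail' iff failed_rules non-empty")


def filter_indels(tumor_alt: int, tumor_depth: int,
                  normal_alt: int | None, normal_depth: int | None, *,
                  min_tumor_af: float = 0.04, max_normal_af: float = 0.02,
                  min_tumor_depth: int = 8, min_normal_depth: int = 6,
                  min_tumor_alt: int = 3, record=None) -> FilterDecision:
    """Consensus-indel thresholds; tumor alt fraction and alt reads are
    strict inequalities, depths are non-strict."""
    failed: list[str] = []
    if normal_alt is None or normal_depth is None:
        return FilterDecision(record, "fail", ["normal-missing"])
    tumor_af = tumor_alt / tumor_depth if tumor_depth > 0 else 0.0
    normal_af = normal_alt / normal_depth if normal_depth > 0 else 0.0
    if not tumor_af > min_tumor_af:
        failed.append(f"tumor-af<= {min_tumor_af}")
    if not normal_af < max_normal_af:
        failed.append(f"normal-af>={max_normal_af}")
    if not tumor_depth >= min_tumor_depth:
        failed.append(f"tumor-depth<{min_tumor_depth}")
    if not normal_depth >= min_normal_depth:
        failed.append(f"normal-depth<{min_normal_depth}")
    if not tumor_alt > min_tumor_alt:
        failed.append(f"tumor-alt<={min_tumor_alt}")
    return FilterDecision(record, "fail" if failed else "pass", failed)


def filter_targeted(tumor_alt: int, tumor_depth: int, *,
                    min_depth: int = 30, min_alt: int = 8,
                    record=None) -> FilterDecision:
    """Deep targeted-sequencing thresholds (both non-strict)."""
    failed: list[str] = []
    if not tumor_depth >= min_depth:
        failed.append(f"depth<{min_depth}")
    if not tumor_alt >= min_alt:
        failed.append(f"alt<{min_alt}")
    return FilterDecision(record, "fail" if failed else "pass", failed)


def classify_driver(consequence: str | None = None,
                    sift: float | None = None,
                    polyphen: float | None = None,
                    cadd_like: float | None = None,
                    hotspot_recurrent: bool = False,
                    hotspot_3d: bool = False,
                    in_driver_gene_list: bool = True, *,
                    sift_max: float = 0.05, polyphen_min: float = 0.995,
                    cadd_min: float = 0.99) -> str:
    """Putative-driver call: 'driver', 'non-driver' or 'not-classifiable'.

    Rule (i): deleterious consequence with SIFT < 0.05 OR PolyPhen > 0.995
    OR CADD-like > 0.99. Rule (ii): recurrent or 3D-clustered hotspot.
    A variant with no scores and no hotspot flags cannot be classified.
    """
    if not in_driver_gene_list:
        return "non-driver"
    has_scores = any(v is not None for v in (sift, polyphen, cadd_like))
    if not has_scores and not (hotspot_recurrent or hotspot_3d):
        return "not-classifiable"
    if hotspot_recurrent or hotspot_3d:
        return "driver"
    if consequence in DELETERIOUS_CONSEQUENCES:
        if ((sift is not None and sift < sift_max)
                or (polyphen is not None and polyphen > polyphen_min)
                or (cadd_like is not None and cadd_like > cadd_min)):
            return "driver"
    return "non-driver"


def classify_driver_batch(rows: Sequence[dict], **kwargs) -> list[str]:
    """Batch driver classification; order-independent, identical to
    record-at-a-time calls."""
    return [classify_driver(**row, **kwargs) for row in rows]


def classify_methylation_change(beta_tumor: float, beta_normal: float | None, *,
                                threshold: float = 0.20,
                                relative: bool = False) -> str:
    """Hyper/hypo-methylation against the matched normal.

    Absolute reading (default): hyper iff beta_t - beta_n >= 0.20, hypo iff
    <= -0.20. Relative reading: +-20% of the normal beta.
    """
    if beta_normal is None:
        return "not-classifiable"
    if relative:
        hyper_cut = beta_normal * (1.0 + threshold)
        hypo_cut = beta_normal * (1.0 - threshold)
        if beta_tumor >= hyper_cut and beta_normal > 0:
            return "hyper"
        if beta_tumor <= hypo_cut:
            return "hypo"
        return "none"
    delta = beta_tumor - beta_normal
    if delta >= threshold - 1e-12:      # guard against float representation
        return "hyper"
    if delta <= -threshold + 1e-12:
        return "hypo"
    return "none"


def load_driver_genes(path: str | Path) -> set[str]:
    """Driver-gene list: plain text, one gene symbol per line, '#' comments."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


#: small illustrative kidney-cancer driver list (not the full targeted panel)
DEFAULT_DRIVER_GENES = frozenset({
    "MET", "SETD2", "PBRM1", "NF2", "SMARCB1", "TERT", "ATM", "IDH1",
    "EP300", "KMT2A", "KMT2C", "NFE2L2", "VHL", "ROS1", "BAP1", "TP53",
})
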