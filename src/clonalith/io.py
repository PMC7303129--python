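"""Readers, writers and in-memory containers for the per-tumor data bundle.

A tumor bundle consists of:

* a sample manifest (YAML or JSON) naming the tumor, its regional samples,
  their roles (primary / metastasis / normal), purity and spatial index;
* a multi-sample somatic VCF (4.2) with per-sample allele depths;
* an allele-specific copy-number segment table (TSV, 1-based inclusive);
* structural variants in BEDPE (0-based half-open breakpoint intervals);
* a methylation beta matrix (TSV, probes x samples) with a probe
  genomic-context annotation sidecar.

Only ``FILTER == PASS`` VCF rows are ingested by default, matching the
convention of keeping calls flagged Somatic/PASS by the upstream caller.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import BundleError, InvariantViolation, ParseError

log = logging.getLogger(__name__)

SAMPLE_ROLES = ("primary", "metastasis", "normal")

#: closed vocabulary of allele-specific copy-number states
SEGMENT_STATES = ("HOMD", "DLOH", "HET", "NLOH", "ALOH", "ASCNA", "BCNA", "amp")

SV_TYPES = ("deletion", "tandem_dup", "translocation", "inversion")

#: closed vocabulary of probe genomic contexts
METH_CONTEXTS = (
    "intergenic", "1to5kb", "promoters", "5'UTRs", "first exon",
    "exon-intron boundary", "exons", "introns", "intron-exon boundary",
    "3'UTRs", "lncRNA", "enhancers",
)

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "total", "major", "minor", "frac", "state"]

#: optional variant annotation columns recognised throughout the package
ANNOTATION_COLUMNS = [
    "gene", "consequence", "sift", "polyphen", "cadd_like",
    "hotspot_recurrent", "hotspot_3d", "context",
]


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    sample_id: str
    role: str
    purity: float | None = None
    spatial_index: int | None = None


@dataclass
class SampleManifest:
    """Samples of one tumor: regional primaries, optional metastases, normals."""

    tumor_id: str
    samples: list[Sample]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise BundleError(f"duplicate sample IDs in manifest for {self.tumor_id}")
        for s in self.samples:
            if s.role not in SAMPLE_ROLES:
                raise BundleError(f"unknown sample role {s.role!r} for {s.sample_id}")
            if s.purity is not None and not (0.0 < s.purity <= 1.0):
                raise BundleError(f"purity {s.purity} out of (0,1] for {s.sample_id}")
        if not any(s.role == "primary" for s in self.samples):
            raise BundleError(f"manifest for {self.tumor_id} has no primary sample")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def tumor_samples(self) -> list[str]:
        """Primary + metastasis sample IDs, primaries first, by spatial index."""
        prim = [s for s in self.samples if s.role == "primary"]
        mets = [s for s in self.samples if s.role == "metastasis"]
        key = lambda s: (s.spatial_index if s.spatial_index is not None else 10**9, s.sample_id)
        return [s.sample_id for s in sorted(prim, key=key)] + \
               [s.sample_id for s in sorted(mets, key=key)]

    @property
    def normal_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.role == "normal"]

    @property
    def reference_normal(self) -> str | None:
        """The designated reference normal (the most distant one: highest
        spatial index among normals, mirroring the study design)."""
        normals = [s for s in self.samples if s.role == "normal"]
        if not normals:
            return None
        key = lambda s: (-(s.spatial_index if s.spatial_index is not None else -1), s.sample_id)
        return sorted(normals, key=key)[0].sample_id

    def purity(self, sample_id: str) -> float | None:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.purity
        raise KeyError(sample_id)


def read_manifest(path: str | Path) -> SampleManifest:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        samples = [
            Sample(
                sample_id=str(s["sample_id"]),
                role=str(s["role"]),
                purity=(None if s.get("purity") is None else float(s["purity"])),
                spatial_index=(None if s.get("spatial_index") is None else int(s["spatial_index"])),
            )
            for s in data["samples"]
        ]
        return SampleManifest(tumor_id=str(data["tumor_id"]), samples=samples)
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed manifest: {exc}", path=str(path)) from exc


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    data = {
        "tumor_id": manifest.tumor_id,
        "samples": [
            {"sample_id": s.sample_id, "role": s.role, "purity": s.purity,
             "spatial_index": s.spatial_index}
            for s in manifest.samples
        ],
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass
class MultiRegionVariantSet:
    """Somatic variants with per-sample read counts across regions of one tumor.

    ``variants`` holds one row per variant (chrom, pos, ref, alt, var_class
    plus optional annotation columns); ``ref_counts`` / ``alt_counts`` are
    aligned variant x sample integer frames.
    """

    variants: pd.DataFrame
    ref_counts: pd.DataFrame
    alt_counts: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        need = {"chrom", "pos", "ref", "alt", "var_class"}
        missing = need - set(self.variants.columns)
        if missing:
            raise InvariantViolation(f"variant table missing columns {sorted(missing)}")
        if not (self.ref_counts.index.equals(self.variants.index)
                and self.alt_counts.index.equals(self.variants.index)):
            raise InvariantViolation("count frames not aligned to variant table")
        if list(self.ref_counts.columns) != list(self.alt_counts.columns):
            raise InvariantViolation("ref/alt count frames have different samples")
        if (self.ref_counts.to_numpy() < 0).any() or (self.alt_counts.to_numpy() < 0).any():
            raise InvariantViolation("negative read counts")

    @property
    def samples(self) -> list[str]:
        return list(self.ref_counts.columns)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def depth(self) -> pd.DataFrame:
        return self.ref_counts + self.alt_counts

    @property
    def vaf(self) -> pd.DataFrame:
        depth = self.depth.to_numpy(dtype=float)
        alt = self.alt_counts.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        return pd.DataFrame(v, index=self.variants.index, columns=self.samples)

    def subset_samples(self, samples: Sequence[str]) -> "MultiRegionVariantSet":
        return MultiRegionVariantSet(
            self.variants.copy(),
            self.ref_counts[list(samples)].copy(),
            self.alt_counts[list(samples)].copy(),
        )


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

@dataclass
class SegmentProfile:
    """Allele-specific copy-number segments, all samples of one tumor.

    Coordinates are 1-based inclusive; ``total = major + minor`` and segments
    must not overlap within a sample.
    """

    df: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.validate()
        self._build_index()

    def validate(self) -> None:
        missing = set(SEGMENT_COLUMNS) - set(self.df.columns)
        if missing:
            raise InvariantViolation(f"segment table missing columns {sorted(missing)}")
        d = self.df
        if (d["start"] > d["end"]).any():
            raise InvariantViolation("segment with start > end")
        if (d["minor"] > d["major"]).any() or (d["minor"] < 0).any():
            raise InvariantViolation("segment must satisfy major >= minor >= 0")
        if (d["total"] != d["major"] + d["minor"]).any():
            raise InvariantViolation("segment total != major + minor")
        bad_state = set(d["state"]) - set(SEGMENT_STATES)
        if bad_state:
            raise InvariantViolation(f"unknown segment states {sorted(bad_state)}")
        for (sample, chrom), grp in d.groupby(["sample", "chrom"], sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
                raise InvariantViolation(
                    f"overlapping segments for sample {sample} chrom {chrom}")

    def _build_index(self) -> None:
        self._index = {}
        for (sample, chrom), grp in self.df.groupby(["sample", "chrom"], sort=False):
            g = grp.sort_values("start")
            self._index[(sample, str(chrom))] = (
                g["start"].to_numpy(), g["end"].to_numpy(), g.index.to_numpy())

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.df["sample"]))

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.df[self.df["sample"] == sample]

    def locate(self, sample: str, chrom: str, pos: int) -> pd.Series | None:
        """The unique segment covering (chrom, pos) in ``sample``, or None."""
        key = (sample, str(chrom))
        if key not in self._index:
            return None
        starts, ends, idx = self._index[key]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos <= ends[i]:
            return self.df.loc[idx[i]]
        return None


def locate_segment(profile: SegmentProfile, sample: str, chrom: str, pos: int):
    """Module-level convenience wrapper around :meth:`SegmentProfile.locate`."""
    return profile.locate(sample, chrom, pos)


def read_segments(path: str | Path) -> SegmentProfile:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse segment table: {exc}", path=str(path)) from exc
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"segment table missing columns {sorted(missing)}", path=str(path))
    for col in ("start", "end", "total", "major", "minor"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ParseError(f"non-numeric {col!r}", path=str(path),
                             line=int(bad.idxmax()) + 2)
        df[col] = df[col].astype(int)
    df["frac"] = df["frac"].astype(float)
    return SegmentProfile(df)


def write_segments(profile: SegmentProfile, path: str | Path) -> None:
    profile.df.to_csv(path, sep="\t", index=False, columns=SEGMENT_COLUMNS,
                      float_format="%.10g")


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------

@dataclass
class SVSet:
    """Breakpoint-pair structural variants with per-sample presence flags.

    ``events`` has one row per SV (chrom1, pos1, chrom2, pos2, sv_type, size;
    positions 1-based); ``presence`` is an event x sample boolean frame;
    ``ccf`` (optional) an aligned float frame of per-region cancer cell
    fractions.
    """

    events: pd.DataFrame
    presence: pd.DataFrame
    ccf: pd.DataFrame | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        need = {"chrom1", "pos1", "chrom2", "pos2", "sv_type", "size"}
        missing = need - set(self.events.columns)
        if missing:
            raise InvariantViolation(f"SV table missing columns {sorted(missing)}")
        bad = set(self.events["sv_type"]) - set(SV_TYPES)
        if bad:
            raise InvariantViolation(f"unknown SV types {sorted(bad)}")
        intra = self.events["chrom1"] == self.events["chrom2"]
        if (self.events.loc[intra, "size"] <= 0).any():
            raise InvariantViolation("intra-chromosomal SV with size <= 0")
        if not self.presence.index.equals(self.events.index):
            raise InvariantViolation("presence frame not aligned to events")
        if self.ccf is not None and not self.ccf.index.equals(self.events.index):
            raise InvariantViolation("ccf frame not aligned to events")

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    def __len__(self) -> int:
        return len(self.events)


def empty_svset(samples: Sequence[str]) -> SVSet:
    events = pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2", "sv_type", "size"])
    presence = pd.DataFrame(columns=list(samples), dtype=bool)
    return SVSet(events, presence)


def read_bedpe(path: str | Path) -> SVSet:
    """Read SVs from a headered BEDPE (0-based half-open breakpoint intervals).

    Columns after strand2: ``sv_type`` then ``present:<sample>`` 0/1 flags and
    optional ``ccf:<sample>`` columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    if df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    need = {"chrom1", "start1", "end1", "chrom2", "start2", "end2", "sv_type"}
    missing = need - set(df.columns)
    if missing:
        raise ParseError(f"BEDPE missing columns {sorted(missing)}", path=str(path))
    if ((df["end1"] - df["start1"]) != 1).any() or ((df["end2"] - df["start2"]) != 1).any():
        raise ParseError("breakpoints must be single-base half-open intervals",
                         path=str(path))
    events = pd.DataFrame({
        "chrom1": df["chrom1"], "pos1": df["start1"].astype(int) + 1,
        "chrom2": df["chrom2"], "pos2": df["start2"].astype(int) + 1,
        "sv_type": df["sv_type"],
    })
    intra = events["chrom1"] == events["chrom2"]
    events["size"] = np.where(intra, (events["pos2"] - events["pos1"]).abs(), 0)
    pres_cols = [c for c in df.columns if c.startswith("present:")]
    ccf_cols = [c for c in df.columns if c.startswith("ccf:")]
    presence = df[pres_cols].astype(int).astype(bool)
    presence.columns = [c.split(":", 1)[1] for c in pres_cols]
    ccf = None
    if ccf_cols:
        ccf = df[ccf_cols].astype(float)
        ccf.columns = [c.split(":", 1)[1] for c in ccf_cols]
    return SVSet(events, presence, ccf)


def write_bedpe(svs: SVSet, path: str | Path) -> None:
    ev = svs.events
    out = pd.DataFrame({
        "#chrom1": ev["chrom1"], "start1": ev["pos1"] - 1, "end1": ev["pos1"],
        "chrom2": ev["chrom2"], "start2": ev["pos2"] - 1, "end2": ev["pos2"],
        "sv_type": ev["sv_type"],
    })
    for s in svs.samples:
        out[f"present:{s}"] = svs.presence[s].astype(int)
    if svs.ccf is not None:
        for s in svs.ccf.columns:
            out[f"ccf:{s}"] = svs.ccf[s]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Methylation beta values (probes x samples) plus probe annotations.

    ``probe_annotation`` carries a ``context`` label from the closed genomic
    context vocabulary and a boolean ``cpg_island`` flag per probe.
    """

    values: pd.DataFrame
    probe_annotation: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise InvariantViolation("beta values outside [0, 1]")
        if not self.probe_annotation.index.equals(self.values.index):
            raise InvariantViolation("probe annotation not aligned to beta matrix")
        bad = set(self.probe_annotation["context"]) - set(METH_CONTEXTS)
        if bad:
            raise InvariantViolation(f"unknown genomic contexts {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probes(self) -> pd.Index:
        return self.values.index


def read_beta(path: str | Path, annotation_path: str | Path) -> BetaMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    if "cpg_island" in ann.columns:
        ann["cpg_island"] = ann["cpg_island"].astype(bool)
    return BetaMatrix(values, ann)


def write_beta(beta: BetaMatrix, path: str | Path, annotation_path: str | Path) -> None:
    beta.values.to_csv(path, sep="\t", float_format="%.10g")
    ann = beta.probe_annotation.copy()
    ann["cpg_island"] = ann["cpg_island"].astype(int)
    ann.to_csv(annotation_path, sep="\t")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_KEYS = {  # VCF INFO key -> annotation column
    "GENE": "gene", "CSQ": "consequence", "SIFT": "sift", "POLYPHEN": "polyphen",
    "CADD": "cadd_like", "HOTSPOT": "hotspot_recurrent", "HOTSPOT3D": "hotspot_3d",
    "CTX": "context",
}
_FLAG_KEYS = {"HOTSPOT", "HOTSPOT3D"}


def read_vcf(path: str | Path, pass_only: bool = True) -> MultiRegionVariantSet:
    """Read a multi-sample somatic VCF into a :class:`MultiRegionVariantSet`.

    Per-sample counts come from the AD field; when AD is absent, DP and AF are
    used instead (MuTect2-style output). Only PASS rows are kept by default.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, refs, alts = [], [], []
    for var in vcf:
        if pass_only and var.FILTER is not None:  # cyvcf2: PASS -> None
            continue
        ref, alt = var.REF, var.ALT[0]
        var_class = "SNV" if len(ref) == 1 and len(alt) == 1 else "indel"
        row = {"chrom": var.CHROM, "pos": var.POS, "ref": ref, "alt": alt,
               "var_class": var_class}
        for key, col in _INFO_KEYS.items():
            val = var.INFO.get(key)
            if val is not None:
                row[col] = bool(val) if key in _FLAG_KEYS else val
        rows.append(row)
        ad = None
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            refs.append(ad[:, 0].astype(int))
            alts.append(ad[:, 1].astype(int))
        else:
            dp = var.format("DP")
            af = var.format("AF")
            if dp is None or af is None:
                raise ParseError("VCF record has neither AD nor DP+AF",
                                 path=str(path))
            alt_n = np.rint(dp[:, 0].astype(float) * af[:, 0].astype(float)).astype(int)
            refs.append(dp[:, 0].astype(int) - alt_n)
            alts.append(alt_n)
    variants = pd.DataFrame(rows)
    if len(variants) == 0:
        variants = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "var_class"])
        empty = pd.DataFrame(np.zeros((0, len(samples)), dtype=int), columns=samples)
        return MultiRegionVariantSet(variants, empty, empty.copy())
    ref_counts = pd.DataFrame(np.vstack(refs), columns=samples, index=variants.index)
    alt_counts = pd.DataFrame(np.vstack(alts), columns=samples, index=variants.index)
    return MultiRegionVariantSet(variants, ref_counts, alt_counts)


def write_vcf(vset: MultiRegionVariantSet, path: str | Path,
              contigs: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with AD/DP per sample and PASS filters."""
    lines = ["##fileformat=VCFv4.2", "##source=clonalith"]
    if contigs:
        for chrom, length in contigs.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
        '##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score">',
        '##INFO=<ID=POLYPHEN,Number=1,Type=Float,Description="PolyPhen score">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="Normalized deleteriousness score">',
        '##INFO=<ID=HOTSPOT,Number=0,Type=Flag,Description="Recurrent hotspot">',
        '##INFO=<ID=HOTSPOT3D,Number=0,Type=Flag,Description="3D clustered hotspot">',
        '##INFO=<ID=CTX,Number=1,Type=String,Description="Genomic context">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(vset.samples),
    ]
    ref = vset.ref_counts.to_numpy()
    alt = vset.alt_counts.to_numpy()
    inv_keys = {v: k for k, v in _INFO_KEYS.items()}
    for i, (_, row) in enumerate(vset.variants.iterrows()):
        info_parts = []
        for col in ANNOTATION_COLUMNS:
            if col in vset.variants.columns:
                val = row[col]
                if pd.isna(val) if not isinstance(val, (bool, np.bool_)) else not val:
                    continue
                key = inv_keys[col]
                if key in _FLAG_KEYS:
                    if val:
                        info_parts.append(key)
                elif isinstance(val, float):
                    info_parts.append(f"{key}={val:.6g}")
                else:
                    info_parts.append(f"{key}={val}")
        info = ";".join(info_parts) if info_parts else "."
        fmt = "\t".join(f"{ref[i, j]},{alt[i, j]}:{ref[i, j] + alt[i, j]}"
                        for j in range(len(vset.samples)))
        lines.append(f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                     f"\t.\tPASS\t{info}\tAD:DP\t{fmt}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class TumorBundle:
    """All per-tumor inputs, cross-validated against the manifest."""

    manifest: SampleManifest
    variants: MultiRegionVariantSet
    segments: SegmentProfile | None
    svs: SVSet
    betas: BetaMatrix | None

    def tumor_variant_set(self) -> MultiRegionVariantSet:
        keep = [s for s in self.manifest.tumor_samples if s in self.variants.samples]
        return self.variants.subset_samples(keep)


def _check_samples(kind: str, found: Iterable[str], manifest: SampleManifest) -> None:
    extra = set(found) - set(manifest.sample_ids)
    if extra:
        raise BundleError(
            f"{kind} contains sample(s) not in manifest: {', '.join(sorted(extra))}")


def read_bundle(manifest_path, vcf_path, segments_path=None, sv_path=None,
                beta_path=None, beta_annotation_path=None,
                pass_only: bool = True) -> TumorBundle:
    """Assemble and cross-validate the per-tumor data bundle.

    Missing optional components yield empty/None members with a logged
    warning; a sample-ID mismatch raises :class:`BundleError` naming the
    offending sample.
    """
    manifest = read_manifest(manifest_path)
    variants = read_vcf(vcf_path, pass_only=pass_only)
    _check_samples("VCF", variants.samples, manifest)

    segments = None
    if segments_path is not None and Path(segments_path).exists():
        segments = read_segments(segments_path)
        _check_samples("segment table", segments.samples, manifest)
    else:
        log.warning("no segment table for %s; copy-number analyses disabled",
                    manifest.tumor_id)

    if sv_path is not None and Path(sv_path).exists():
        svs = read_bedpe(sv_path)
        _check_samples("BEDPE", svs.samples, manifest)
    else:
        log.warning("no SV file for %s; SV analyses will see zero events",
                    manifest.tumor_id)
        svs = empty_svset(manifest.tumor_samples)

    betas = None
    if beta_path is not None and Path(beta_path).exists():
        betas = read_beta(beta_path, beta_annotation_path)
        _check_samples("beta matrix", betas.samples, manifest)
    else:
        log.warning("no methylation matrix for %s", manifest.tumor_id)

    return TumorBundle(manifest, variants, segments, svs, betas)


def write_bundle(bundle: TumorBundle, outdir: str | Path,
                 contigs: Mapping[str, int] | None = None) -> dict[str, Path]:
    """Write all bundle components into ``outdir``; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": outdir / "manifest.yaml",
        "vcf": outdir / "variants.vcf",
        "segments": outdir / "segments.tsv",
        "svs": outdir / "svs.bedpe",
        "beta": outdir / "beta.tsv",
        "beta_annotation": outdir / "beta_annotation.tsv",
    }
    write_manifest(bundle.manifest, paths["manifest"])
    write_vcf(bundle.variants, paths["vcf"], contigs=contigs)
    if bundle.segments is not None:
        write_segments(bundle.segments, paths["segments"])
    if len(bundle.svs):
        write_bedpe(bundle.svs, paths["svs"])
    if bundle.betas is not None:
        write_beta(bundle.betas, paths["beta"], paths["beta_annotation"])
    return paths
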