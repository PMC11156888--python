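"""YAML run-manifest parsing and validation.

A run is described by one manifest naming the reference, the samples (with
barcodes, FASTQ paths, guide, dsODN and biological replicate group), guide
and dsODN definitions, optional amplicon definitions, parameter overrides
and an optional ``simulate`` block. Validation collects *all* problems and
reports them together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Optional

import yaml

from .ampliconq import AmpliconSpec
from .seqio import Sample, SampleManifest
from .sitecall import GuideSpec
from .tagscan import DEFAULT_DSODNS, DsODNSpec


class ManifestError(ValueError):
    """Raised with every validation problem listed at once."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid manifest:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass
class Params:
    """Pipeline parameter overrides with documented defaults and ranges."""

    max_barcode_mm: int = 1
    umi_length: int = 8
    max_anchor_mm: int = 1
    min_fragment_length: int = 25
    k: int = 20
    max_fragment_mm: int = 3
    merge_window: int = 10
    flank: int = 25
    max_mismatches: int = 7  # combined protospacer+PAM mismatch budget
    min_replicates: int = 2
    locus_tolerance: int = 10

    _RANGES = {
        "max_barcode_mm": (0, 3),
        "umi_length": (4, 16),
        "max_anchor_mm": (0, 3),
        "min_fragment_length": (10, 100),
        "k": (10, 32),
        "max_fragment_mm": (0, 10),
        "merge_window": (0, 100),
        "flank": (5, 200),
        "max_mismatches": (0, 15),
        "min_replicates": (1, 10),
        "locus_tolerance": (0, 100),
    }

    def validate(self, problems: list[str]) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not isinstance(v, int) or not lo <= v <= hi:
                problems.append(f"params.{name}={v!r} outside [{lo}, {hi}]")


@dataclass
class RunManifest:
    reference: Optional[str]
    output_dir: str
    samples: SampleManifest
    guides: dict[str, GuideSpec]
    dsodns: dict[str, DsODNSpec]
    amplicons: list[AmpliconSpec] = field(default_factory=list)
    params: Params = field(default_factory=Params)
    simulate: Optional[dict] = None
    seed: int = 0


_TOP_KEYS = {"reference", "output_dir", "samples", "guides", "dsodns",
             "amplicons", "params", "simulate", "seed"}
_SAMPLE_KEYS = {"id", "barcode", "r1", "r2", "guide", "dsodn", "replicate_group"}
_GUIDE_KEYS = {"name", "protospacer", "pam", "cut_offset", "on_target"}
_DSODN_KEYS = {"name", "sequence", "anchor_length"}
_AMPLICON_KEYS = {"site_name", "reference_amplicon", "target_anchor", "dsodn", "fastq"}


def _check_keys(d: dict, allowed: set, where: str, problems: list[str]) -> None:
    for k in d:
        if k not in allowed:
            problems.append(f"unknown key {k!r} in {where}")


def validate_manifest(path, check_paths: bool = True) -> RunManifest:
    """Parse and fully validate a YAML manifest; hard error listing all
    problems at once. ``check_paths=False`` skips file-existence checks
    (used when the manifest describes data yet to be simulated)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ManifestError(["manifest is not a YAML mapping"])
    problems: list[str] = []
    _check_keys(doc, _TOP_KEYS, "manifest", problems)

    base = path.parent

    def resolve(p: Optional[str]) -> Optional[str]:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    dsodns: dict[str, DsODNSpec] = {}
    for name, seq in DEFAULT_DSODNS.items():
        dsodns[name] = DsODNSpec(name=name, sequence=seq)
    for d in doc.get("dsodns", []) or []:
        _check_keys(d, _DSODN_KEYS, f"dsodn {d.get('name')}", problems)
        try:
            spec = DsODNSpec(
                name=str(d.get("name", "")),
                sequence=str(d.get("sequence", "")),
                anchor_length=int(d.get("anchor_length", 12)),
            )
            dsodns[spec.name] = spec
        except (ValueError, TypeError) as e:
            problems.append(f"dsodn {d.get('name')!r}: {e}")

    guides: dict[str, GuideSpec] = {}
    for g in doc.get("guides", []) or []:
        _check_keys(g, _GUIDE_KEYS, f"guide {g.get('name')}", problems)
        try:
            on = g.get("on_target")
            on_target = (str(on["contig"]), int(on["position"])) if on else None
            spec = GuideSpec(
                name=str(g.get("name", "")),
                protospacer=str(g.get("protospacer", "")),
                pam=str(g.get("pam", "NGG")),
                cut_offset=int(g.get("cut_offset", 3)),
                on_target=on_target,
            )
            guides[spec.name] = spec
        except (ValueError, TypeError, KeyError) as e:
            problems.append(f"guide {g.get('name')!r}: {e}")

    samples: list[Sample] = []
    barcode_owner: dict[str, str] = {}
    for s in doc.get("samples", []) or []:
        _check_keys(s, _SAMPLE_KEYS, f"sample {s.get('id')}", problems)
        sid = str(s.get("id", ""))
        bc = str(s.get("barcode", "")).upper()
        if not sid:
            problems.append("sample with missing id")
        if not bc:
            problems.append(f"sample {sid}: missing barcode")
        elif bc in barcode_owner:
            problems.append(
                f"samples {barcode_owner[bc]!r} and {sid!r} share barcode {bc}")
        else:
            barcode_owner[bc] = sid
        for key in ("guide", "dsodn"):
            ref = s.get(key)
            pool = guides if key == "guide" else dsodns
            if ref is not None and ref not in pool:
                problems.append(f"sample {sid}: unknown {key} {ref!r}")
        for key in ("r1", "r2"):
            p = resolve(s.get(key))
            if check_paths and p is not None and not Path(p).exists():
                problems.append(f"sample {sid}: {key} path does not exist: {p}")
        if not s.get("replicate_group"):
            problems.append(f"sample {sid}: replicate_group must be non-empty")
        try:
            samples.append(
                Sample(
                    sample_id=sid,
                    barcode=bc or "A",
                    r1=resolve(s.get("r1")),
                    r2=resolve(s.get("r2")),
                    guide_name=str(s.get("guide", "")),
                    dsodn_name=str(s.get("dsodn", "")),
                    replicate_group=str(s.get("replicate_group", "")),
                )
            )
        except ValueError as e:
            problems.append(f"sample {sid}: {e}")

    amplicons: list[AmpliconSpec] = []
    for a in doc.get("amplicons", []) or []:
        _check_keys(a, _AMPLICON_KEYS, f"amplicon {a.get('site_name')}", problems)
        try:
            dsodn = dsodns.get(str(a.get("dsodn", "")))
            if dsodn is None:
                problems.append(f"amplicon {a.get('site_name')}: unknown dsodn")
                continue
            spec = AmpliconSpec(
                site_name=str(a.get("site_name", "")),
                reference_amplicon=str(a.get("reference_amplicon", "")),
                target_anchor=str(a.get("target_anchor", "")),
                dsodn=dsodn,
            )
            spec.fastq = resolve(a.get("fastq"))  # type: ignore[attr-defined]
            amplicons.append(spec)
        except ValueError as e:
            problems.append(f"amplicon {a.get('site_name')!r}: {e}")

    params = Params()
    pdoc = doc.get("params", {}) or {}
    known = {f.name for f in dc_fields(Params)}
    for k, v in pdoc.items():
        if k not in known:
            problems.append(f"unknown key {k!r} in params")
        else:
            setattr(params, k, v)
    params.validate(problems)

    reference = resolve(doc.get("reference"))
    if check_paths and reference is not None and not Path(reference).exists():
        problems.append(f"reference path does not exist: {reference}")

    if len({len(s.barcode) for s in samples} or {0}) > 1:
        problems.append("sample barcodes must all have the same length")

    if problems:
        raise ManifestError(problems)

    return RunManifest(
        reference=reference,
        output_dir=resolve(doc.get("output_dir", "dsbtag_out")) or "dsbtag_out",
        samples=SampleManifest(samples),
        guides=guides,
        dsodns=dsodns,
        amplicons=amplicons,
        params=params,
        simulate=doc.get("simulate"),
        seed=int(doc.get("seed", 0)),
    )
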