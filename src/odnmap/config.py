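"""Run configuration: samples, guides, ODN/primer design, and scan parameters.

The configuration binds together everything one sequencing run needs: the
per-sample barcodes and treatment labels, the guide RNAs with their PAM
patterns, the dsODN amplicon grammar (primers + reporter), and the defaults
of the downstream filters (14/20 matched bases, exact PAM, 100 bp window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dna import IUPAC, validate_alphabet

#: Synthetic default dsODN (46 nt) with nested primers and 3'-terminal
#: reporter. The real oligo set is study-specific configuration; this default
#: exists so the pipeline and its tests are self-contained. Layout:
#: [outer primer1][inner primer2][reporter], reporter 3' end = genome junction.
DEFAULT_ODN_SEQ = "ATGGCTAGCTTGCAGGTACCTGAACGTTCAGGACTCGATTCGTGAC"
DEFAULT_PRIMER1 = DEFAULT_ODN_SEQ[0:16]     # ATGGCTAGCTTGCAGG
DEFAULT_PRIMER2 = DEFAULT_ODN_SEQ[16:34]    # TACCTGAACGTTCAGGAC
DEFAULT_REPORTER = DEFAULT_ODN_SEQ[34:46]   # TCGATTCGTGAC

#: Synthetic ligated-adapter remnant expected at the 5' end of the
#: adapter-side read (after the sample barcode).
DEFAULT_ADAPTER = "ACACTCTTTCCC"


class ConfigError(ValueError):
    """Raised for malformed or inconsistent run configuration."""


@dataclass(frozen=True)
class GuideSpec:
    """A nuclease target: protospacer + PAM pattern + cut geometry.

    ``cut_offset`` is the signed distance (bp) of the blunt cut from the
    PAM-proximal protospacer end; -3 is standard SpCas9 geometry (cut between
    protospacer bases 17 and 18, 3 bp 5' of the PAM).
    """

    name: str
    protospacer: str
    pam: str = "NGG"
    cut_offset: int = -3

    def __post_init__(self) -> None:
        validate_alphabet(self.protospacer, "ACGT", f"protospacer of guide {self.name!r}")
        for code in self.pam:
            if code not in IUPAC:
                raise ConfigError(f"guide {self.name!r}: PAM symbol {code!r} is not IUPAC")


@dataclass(frozen=True)
class OdnSpec:
    """The dsODN amplicon grammar: full oligo, nested primers, and reporter.

    The reporter is the ODN segment retained between the inner primer and the
    ODN-genome junction; its presence in a read certifies priming on the ODN.
    """

    odn_seq: str = DEFAULT_ODN_SEQ
    reporter: str = DEFAULT_REPORTER
    primer1: str = DEFAULT_PRIMER1
    primer2: str = DEFAULT_PRIMER2
    adapter: str = DEFAULT_ADAPTER
    reporter_max_mismatch: int = 1
    primer_max_mismatch: int = 2

    def __post_init__(self) -> None:
        for what, seq in (("odn_seq", self.odn_seq), ("reporter", self.reporter),
                          ("primer1", self.primer1), ("primer2", self.primer2),
                          ("adapter", self.adapter)):
            validate_alphabet(seq, "ACGT", what)
        if self.reporter not in self.odn_seq:
            raise ConfigError("reporter must be a substring of odn_seq")
        p2 = self.odn_seq.find(self.primer2)
        rep = self.odn_seq.rfind(self.reporter)
        if p2 < 0 or p2 + len(self.primer2) > rep:
            raise ConfigError("primer2 must bind within odn_seq 5' of the reporter (nested design)")


VALID_TREATMENTS = ("nuclease+ODN", "ODN-only", "no-ODN")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    barcode: str
    treatment: str = "nuclease+ODN"

    def __post_init__(self) -> None:
        validate_alphabet(self.barcode, "ACGT", f"barcode of sample {self.sample_id!r}")
        if self.treatment not in VALID_TREATMENTS:
            raise ConfigError(
                f"sample {self.sample_id!r}: treatment {self.treatment!r} "
                f"not in {VALID_TREATMENTS}")


@dataclass
class RunConfig:
    """Everything a run needs, with the published filter values as defaults.

    Defaults: ``match_min=14`` of 20 protospacer bases, exact PAM match, and
    guide-to-site assignment within ``match_window=100`` bp.
    """

    samples: list[SampleSpec] = field(default_factory=list)
    guides: list[GuideSpec] = field(default_factory=list)
    odn: OdnSpec = field(default_factory=OdnSpec)
    genome_path: str | None = None
    match_min: int = 14
    protospacer_len: int = 20
    match_window: int = 100
    cluster_gap: int = 25
    seed: int = 1

    def __post_init__(self) -> None:
        if self.match_min > self.protospacer_len:
            raise ConfigError(
                f"match_min ({self.match_min}) exceeds protospacer_len ({self.protospacer_len})")
        if self.match_window < 0:
            raise ConfigError("match_window must be >= 0")
        if self.cluster_gap < 0:
            raise ConfigError("cluster_gap must be >= 0")
        barcodes = [s.barcode for s in self.samples]
        dupes = {b for b in barcodes if barcodes.count(b) > 1}
        if dupes:
            raise ConfigError(f"duplicate barcodes across samples: {sorted(dupes)}")
        for g in self.guides:
            if len(g.protospacer) != self.protospacer_len:
                raise ConfigError(
                    f"guide {g.name!r}: protospacer length {len(g.protospacer)} "
                    f"!= protospacer_len {self.protospacer_len}")

    def guide(self, name: str) -> GuideSpec:
        for g in self.guides:
            if g.name == name:
                return g
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "samples": [
                {"sample_id": s.sample_id, "barcode": s.barcode, "treatment": s.treatment}
                for s in self.samples
            ],
            "guides": [
                {"name": g.name, "protospacer": g.protospacer, "pam": g.pam,
                 "cut_offset": g.cut_offset}
                for g in self.guides
            ],
            "odn": {
                "odn_seq": self.odn.odn_seq, "reporter": self.odn.reporter,
                "primer1": self.odn.primer1, "primer2": self.odn.primer2,
                "adapter": self.odn.adapter,
                "reporter_max_mismatch": self.odn.reporter_max_mismatch,
                "primer_max_mismatch": self.odn.primer_max_mismatch,
            },
            "genome_path": self.genome_path,
            "match_min": self.match_min,
            "protospacer_len": self.protospacer_len,
            "match_window": self.match_window,
            "cluster_gap": self.cluster_gap,
            "seed": self.seed,
        }


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing required field {key!r} in {where}")
    return mapping[key]


def config_from_dict(data: dict) -> RunConfig:
    """Build a validated RunConfig from a plain mapping (parsed YAML)."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    samples = [
        SampleSpec(
            sample_id=str(_require(s, "sample_id", "sample entry")),
            barcode=str(_require(s, "barcode", "sample entry")).upper(),
            treatment=str(s.get("treatment", "nuclease+ODN")),
        )
        for s in data.get("samples", [])
    ]
    guides = [
        GuideSpec(
            name=str(_require(g, "name", "guide entry")),
            protospacer=str(_require(g, "protospacer", "guide entry")).upper(),
            pam=str(g.get("pam", "NGG")).upper(),
            cut_offset=int(g.get("cut_offset", -3)),
        )
        for g in data.get("guides", [])
    ]
    odn_data = data.get("odn", {})
    odn_kwargs = {}
    for key in ("odn_seq", "reporter", "primer1", "primer2", "adapter"):
        if key in odn_data:
            odn_kwargs[key] = str(odn_data[key]).upper()
    for key in ("reporter_max_mismatch", "primer_max_mismatch"):
        if key in odn_data:
            odn_kwargs[key] = int(odn_data[key])
    return RunConfig(
        samples=samples,
        guides=guides,
        odn=OdnSpec(**odn_kwargs),
        genome_path=data.get("genome_path"),
        match_min=int(data.get("match_min", 14)),
        protospacer_len=int(data.get("protospacer_len", 20)),
        match_window=int(data.get("match_window", 100)),
        cluster_gap=int(data.get("cluster_gap", 25)),
        seed=int(data.get("seed", 1)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration, validate invariants, apply defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed configuration {path}: {exc}") from exc
    return config_from_dict(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
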