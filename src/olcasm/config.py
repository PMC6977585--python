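"""Pipeline configuration: every tunable of every stage, with provenance.

Each parameter carries a provenance flag: ``paper`` for values taken from the
published assembly protocol this pipeline follows (4-kb minimum read length,
the >=10-read coverage-mask threshold, the 8-kb repeat re-analysis limit and
>=3 spanning-chain rule, the 4-14-kb mito chain bounds with <=1,500 unaligned
bases, and the 1,500-bp split overlap), ``chosen`` for values set by this
implementation.  The run log lists every parameter with its flag so the
protocol-derived values are auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional

import yaml

PAPER = "paper"
CHOSEN = "chosen"

#: provenance of every PipelineConfig field
PROVENANCE: Dict[str, str] = {
    "min_read_length": PAPER,
    "genome_size_estimate": CHOSEN,
    "coverage_mask_threshold": PAPER,
    "dust_window": CHOSEN,
    "dust_threshold": CHOSEN,
    "tandem_max_period": CHOSEN,
    "tandem_min_span": CHOSEN,
    "k": CHOSEN,
    "min_seeds": CHOSEN,
    "max_divergence": CHOSEN,
    "min_alignment_length": CHOSEN,
    "end_slack": CHOSEN,
    "max_gap": CHOSEN,
    "span_slack": CHOSEN,
    "min_flank_support": CHOSEN,
    "min_patch_length": CHOSEN,
    "quality_factor": CHOSEN,
    "chimera_max_repeat_length": PAPER,
    "chimera_min_spanning_chains": PAPER,
    "chimera_flank": CHOSEN,
    "segment": CHOSEN,
    "fuzz": CHOSEN,
    "repeat_cov_factor": CHOSEN,
    "mito_min_chain": PAPER,
    "mito_max_chain": PAPER,
    "mito_max_unaligned": PAPER,
    "mito_split_overlap": PAPER,
    "mito_target_length": CHOSEN,
    "min_circ_overlap": CHOSEN,
    "circ_identity": CHOSEN,
    "seed": CHOSEN,
}


@dataclass
class PipelineConfig:
    # set-up
    min_read_length: int = 4000
    genome_size_estimate: int = 100_000
    # masking
    coverage_mask_threshold: int = 10
    dust_window: int = 64
    dust_threshold: float = 2.0
    tandem_max_period: int = 500
    tandem_min_span: int = 100
    # alignment
    k: int = 14
    min_seeds: int = 3
    max_divergence: float = 0.30
    min_alignment_length: int = 600
    end_slack: int = 25
    max_gap: int = 1500
    # patching
    span_slack: int = 100
    min_flank_support: int = 3
    min_patch_length: int = 400
    quality_factor: float = 1.5
    chimera_max_repeat_length: int = 8000
    chimera_min_spanning_chains: int = 3
    chimera_flank: int = 500
    # layout
    segment: int = 100
    fuzz: int = 200
    repeat_cov_factor: float = 2.0
    # mito
    mito_min_chain: int = 4000
    mito_max_chain: int = 14000
    mito_max_unaligned: int = 1500
    mito_split_overlap: int = 1500
    mito_target_length: Optional[int] = None
    min_circ_overlap: int = 500
    circ_identity: float = 0.95
    # misc
    seed: int = 0

    def align_params(self):
        from .overlap import AlignParams

        return AlignParams(k=self.k, min_seeds=self.min_seeds,
                           max_divergence=self.max_divergence,
                           min_alignment_length=self.min_alignment_length,
                           end_slack=self.end_slack, max_gap=self.max_gap)

    def patch_params(self):
        from .patching import PatchParams

        return PatchParams(span_slack=self.span_slack,
                           min_flank_support=self.min_flank_support,
                           min_patch_length=self.min_patch_length,
                           quality_factor=self.quality_factor,
                           segment=self.segment)

    def chimera_rule_params(self):
        from .patching import ChimeraRuleParams

        return ChimeraRuleParams(
            max_repeat_length=self.chimera_max_repeat_length,
            min_spanning_chains=self.chimera_min_spanning_chains,
            flank=self.chimera_flank)

    def layout_params(self):
        from .layout import LayoutParams

        return LayoutParams(segment=self.segment, end_slack=self.end_slack,
                            fuzz=self.fuzz,
                            repeat_cov_factor=self.repeat_cov_factor)

    def mito_params(self):
        from .mito import CircularChainFilter, MitoParams

        return MitoParams(
            chain_filter=CircularChainFilter(self.mito_min_chain,
                                             self.mito_max_chain,
                                             self.mito_max_unaligned),
            split_overlap=self.mito_split_overlap,
            target_length=self.mito_target_length,
            min_circ_overlap=self.min_circ_overlap,
            circ_identity=self.circ_identity)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.from_dict(data or {})

    def provenance_lines(self):
        """(name, value, paper|chosen) for every parameter, for the run log."""
        for f in dataclasses.fields(self):
            yield f.name, getattr(self, f.name), PROVENANCE.get(f.name, CHOSEN)
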