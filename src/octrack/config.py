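"""Aggregate pipeline configuration with lossless YAML round-tripping.

One plain-text hierarchical config file carries every stage's parameters so
runs are reproducible; ``octrack config init`` prints the defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .phantom import PhantomConfig
from .postprocess import PostfilterConfig
from .preprocess import PreprocessConfig
from .segment import SegmentConfig
from .tracking import MatchConfig


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    postfilter: PostfilterConfig = field(default_factory=PostfilterConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            segment=SegmentConfig(**d.get("segment", {})),
            postfilter=PostfilterConfig(**d.get("postfilter", {})),
            match=MatchConfig(**d.get("match", {})),
            phantom=PhantomConfig(**d.get("phantom", {})),
        )

    def to_yaml(self, path: Union[str, Path, None] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text) or {})


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj
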