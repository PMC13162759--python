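"""Shared configuration and paths for the numbered analysis drivers.

Each driver runs one stage standalone on the previous stage's serialized
outputs, so the chain 01 -> 06 reproduces what
``narousal.pipeline.run_full_pipeline`` does in one call.  Small text
artifacts (CSV/JSON) go under ``results/``; the bulky EEG arrays go
under ``scratch/`` as .npy.
"""

from pathlib import Path

from narousal.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
SCRATCH = ROOT / "scratch" / "analysis"

#: one demo-cohort configuration shared by every stage
CONFIG = PipelineConfig(seed=2026)


def config() -> PipelineConfig:
    cfg_path = RESULTS / "config.json"
    if cfg_path.exists():
        return PipelineConfig.load(cfg_path)
    return CONFIG
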