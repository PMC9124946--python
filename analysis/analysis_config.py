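"""Shared configuration for the numbered analysis steps."""

from pathlib import Path

from fairgame.pipeline import RunConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "run"
CONFIG = RunConfig(seed=20, group_sizes={"GrpS": 8, "GrpB": 10, "GrpF": 10})
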