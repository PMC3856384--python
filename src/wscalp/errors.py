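"""Pipeline error type carrying the failing stage name.

Brain extraction failures are almost always marker-generation failures, and
fixing them means tuning the parameters of the step that failed — so every
error surfaced by the pipelines names its stage.
"""

from __future__ import annotations


class PipelineError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
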