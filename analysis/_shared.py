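"""Shared study configuration for the numbered analysis drivers."""

from navscape.config import ArenaConfig
from navscape.pipeline import StudyConfig


def study_config(seed: int, n_per_cell: int) -> StudyConfig:
    """The analysis-scale study: 2-minute single-block arena sessions."""
    return StudyConfig(n_per_cell=n_per_cell,
                       arena=ArenaConfig(session_blocks=1, block_duration=120.0),
                       master_seed=seed)
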