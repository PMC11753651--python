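"""Light in-memory container for a labelled trial collection.

Both :class:`gaitrel.synthetic.SyntheticStudy` and datasets read from disk
expose ``frame_rate`` and ``trials`` (a mapping from (subject, session,
trial) labels to ``{segment_id: SegmentPoseTrajectory}``); the analysis
pipeline is written against that duck-typed surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GaitDataset:
    frame_rate: float
    trials: dict  # (subject, session, trial) -> {segment_id: SegmentPoseTrajectory}
    truth_events: dict | None = None
    truth_params: dict | None = None
    metadata: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)  # unknown fields preserved on read

    def labels(self):
        return sorted(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)
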