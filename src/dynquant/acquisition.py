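"""Camera acquisition parameters shared by the single-molecule modules.

TIRF movies are recorded as discrete frames: an exposure followed by a
readout delay. All event times are therefore quantized to the frame cycle
(exposure + delay); the defaults correspond to 100 ms frames with a 25 ms
delay, i.e. 8 frames per second.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionParams:
    """Frame timing and pixel calibration of a TIRF acquisition.

    Parameters
    ----------
    exposure_s : float
        Camera exposure per frame, seconds.
    delay_s : float
        Readout delay between frames, seconds.
    pixel_size_um : float
        Edge length of one camera pixel in the sample plane, micrometres.
    min_event_frames : int
        Minimum number of frames a binding event must span to be scored.
    """

    exposure_s: float = 0.100
    delay_s: float = 0.025
    pixel_size_um: float = 0.16
    min_event_frames: int = 2

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise ValueError(f"exposure_s must be > 0, got {self.exposure_s}")
        if self.delay_s < 0:
            raise ValueError(f"delay_s must be >= 0, got {self.delay_s}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.min_event_frames < 1:
            raise ValueError(
                f"min_event_frames must be >= 1, got {self.min_event_frames}"
            )

    @property
    def frame_cycle_s(self) -> float:
        """Duration of one full frame cycle (exposure + delay), seconds."""
        return self.exposure_s + self.delay_s

    @property
    def frame_rate(self) -> float:
        """Frames per second (reciprocal of the frame cycle)."""
        return 1.0 / self.frame_cycle_s

    @property
    def min_event_duration_s(self) -> float:
        """Shortest scoreable event duration, seconds."""
        return self.min_event_frames * self.frame_cycle_s


def frame_rate(acquisition: AcquisitionParams) -> float:
    """Frame rate in frames per second for an acquisition."""
    return acquisition.frame_rate
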