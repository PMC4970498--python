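"""Running accumulators shared by the powder, spectrum and profile chains."""

from __future__ import annotations

import numpy as np

__all__ = ["RunningAverage", "powder_accumulate", "accumulate_spectrum"]


class RunningAverage:
    """Numerically stable running mean of equally shaped arrays.

    ``mean`` is None until the first sample arrives; ``count`` tracks how
    many samples contributed.
    """

    def __init__(self) -> None:
        self.mean: np.ndarray | None = None
        self.count: int = 0

    def add(self, sample: np.ndarray) -> "RunningAverage":
        sample = np.asarray(sample, dtype=float)
        if self.mean is None:
            self.mean = sample.copy()
            self.count = 1
        else:
            if sample.shape != self.mean.shape:
                raise ValueError(
                    f"sample shape {sample.shape} != accumulator shape {self.mean.shape}"
                )
            self.count += 1
            self.mean += (sample - self.mean) / self.count
        return self


def powder_accumulate(state: RunningAverage | None, frame: np.ndarray) -> RunningAverage:
    """Fold one hit frame into the virtual powder pattern (running mean).

    Averaging many single-crystal hits approximates a powder ring pattern;
    deviations from radial symmetry indicate flow-aligned samples.
    """
    if state is None:
        state = RunningAverage()
    return state.add(frame)


def accumulate_spectrum(state: RunningAverage | None, spectrum: np.ndarray) -> RunningAverage:
    """Fold one per-event spectrum into the running average spectrum."""
    if state is None:
        state = RunningAverage()
    return state.add(spectrum)
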