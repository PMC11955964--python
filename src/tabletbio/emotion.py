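"""Emotion probability streams as feature series.

The seven per-frame emotion probabilities (anger, disgust, fear,
happiness, neutral, sadness, surprise) are pipeline inputs — produced by
an upstream facial-expression classifier or by the synthetic generator,
never computed here from video.  This module validates them and exposes
them as aligned FeatureSeries, with optional simplex renormalisation.
"""

from __future__ import annotations

import numpy as np

from .features import FeatureSeries
from .io import ChallengeRecord, SessionError, validate_emotions
from .registry import EMOTIONS


def load_emotions(
    challenge: ChallengeRecord, normalise: bool = False
) -> dict[str, FeatureSeries]:
    """Seven aligned emotion series for one challenge.

    With ``normalise`` each frame is rescaled to sum to 1; a zero-sum
    frame is then an error naming the frame index.  Frames already on the
    simplex are unchanged (the rescale is idempotent).
    """
    em = validate_emotions(challenge.emotions, where=f"{challenge.key()} emotion")
    t = em["t"].to_numpy(dtype=float)
    probs = em[list(EMOTIONS)].to_numpy(dtype=float)
    if normalise and len(em):
        sums = probs.sum(axis=1)
        if np.any(sums == 0):
            frame = int(np.argmax(sums == 0))
            raise SessionError(
                f"{challenge.key()} emotion: frame {frame} sums to 0, cannot normalise"
            )
        probs = probs / sums[:, None]
    return {
        name: FeatureSeries(name, t, probs[:, i] if len(em) else np.empty(0))
        for i, name in enumerate(EMOTIONS)
    }
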