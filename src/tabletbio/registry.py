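"""Fixed registries shared across the pipeline.

The feature registry defines the 16 biometric features (4 eye-tracking,
5 digit-tracking, 7 emotion probabilities) and the canonical, feature-major
column order used everywhere downstream.  The measure registry lists the
15 neuropsychological target variables (10 WISC-V subtests plus 5
questionnaire scores) that the association stage regresses on the
biometric constructs.
"""

from __future__ import annotations

# Emotion labels in their fixed, documented column order.
EMOTIONS: tuple[str, ...] = (
    "anger",
    "disgust",
    "fear",
    "happiness",
    "neutral",
    "sadness",
    "surprise",
)

EYE_FEATURES: tuple[str, ...] = (
    "angular_distance",
    "total_angular_distance",
    "angular_velocity",
    "saccade",
)

TOUCH_FEATURES: tuple[str, ...] = (
    "touch_speed",
    "touch_area",
    "touch_distance",
    "touch_duration",
    "touch_height",
)

EMOTION_FEATURES: tuple[str, ...] = EMOTIONS

#: modality name -> ordered feature names
MODALITY_FEATURES: dict[str, tuple[str, ...]] = {
    "eye": EYE_FEATURES,
    "touch": TOUCH_FEATURES,
    "emotion": EMOTION_FEATURES,
    "multimodal": EYE_FEATURES + TOUCH_FEATURES + EMOTION_FEATURES,
}

MODALITIES: tuple[str, ...] = ("multimodal", "eye", "touch", "emotion")

ALL_FEATURES: tuple[str, ...] = MODALITY_FEATURES["multimodal"]

#: games and their fixed challenge counts
GAME_CHALLENGES: dict[str, int] = {"Rocket": 11, "Connect": 6}
GAMES: tuple[str, ...] = ("Rocket", "Connect")

#: the 10 WISC-V subtest measures
WISC_MEASURES: tuple[str, ...] = (
    "block_design",
    "matrix_reasoning",
    "digit_span",
    "letter_number_sequencing",
    "cancellation",
    "coding",
    "symbol_search",
    "comprehension",
    "similarities",
    "vocabulary",
)

#: questionnaire-derived measures (ADHD scale, CBCL, GSCA, EHI)
QUESTIONNAIRE_MEASURES: tuple[str, ...] = (
    "hyperactivity_impulsivity",
    "inattention",
    "social_problems",
    "achievement",
    "manual_laterality",
)

MEASURES: tuple[str, ...] = WISC_MEASURES + QUESTIONNAIRE_MEASURES

SEXES: tuple[str, ...] = ("girl", "boy")

#: age range covered by the normative table, in years
AGE_RANGE: tuple[float, float] = (7.0, 15.0)

#: number of time bins per feature per challenge
N_BINS: int = 100

#: number of retained principal components ("biometric constructs")
N_COMPONENTS: int = 3

CONSTRUCT_NAMES: tuple[str, ...] = ("MBC1", "MBC2", "MBC3")


def bin_column(feature: str, bin_index: int) -> str:
    """Canonical column name for *feature* at 1-based *bin_index*."""
    return f"{feature}__b{bin_index:03d}"


def matrix_columns(modality: str = "multimodal", n_bins: int = N_BINS) -> list[str]:
    """Feature-major column order of a binned feature matrix."""
    feats = MODALITY_FEATURES[modality]
    return [bin_column(f, b) for f in feats for b in range(1, n_bins + 1)]
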