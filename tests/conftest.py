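import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from rrfdetect import LearnerSpec, SyntheticConfig, Tile, generate_tile
from rrfdetect.pipeline import FEATURE_NAMES, LABEL_COLUMN


def make_tile(pixels: np.ndarray, label: str = "unlabeled") -> Tile:
    return Tile(pixels=np.asarray(pixels, dtype=np.uint8), grid_row=0,
                grid_col=0, source_id="test", label=label)


def solid_tile(rgb: tuple[int, int, int], side: int = 16) -> Tile:
    return make_tile(np.full((side, side, 3), rgb, dtype=np.uint8))


@pytest.fixture
def block_image() -> np.ndarray:
    """Four 2x2 constant blocks: levels 1, 2 / 3, 4."""
    return np.array([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]])


@pytest.fixture
def random_tile() -> Tile:
    rng = np.random.default_rng(42)
    return make_tile(rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8))


@pytest.fixture
def synthetic_tile() -> Tile:
    return generate_tile("ragged", SyntheticConfig(), np.random.default_rng(7))


def gaussian_feature_table(
    n_per_class: dict[str, int], shift: float, seed: int = 0
) -> pd.DataFrame:
    """A 134-column feature table with Gaussian class-conditional features.

    The first five features carry a per-class mean shift of ``shift`` SDs;
    the rest are shared noise.  ``shift = 0`` gives exchangeable classes.
    """
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for k, (label, n) in enumerate(sorted(n_per_class.items())):
        x = rng.normal(size=(n, len(FEATURE_NAMES)))
        x[:, :5] += shift * k
        rows.append(x)
        labels += [label] * n
        ids += [f"{label}-{i}" for i in range(n)]
    table = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES), index=ids)
    table.index.name = "tile_id"
    table[LABEL_COLUMN] = labels
    return table


def cheap_learners() -> list[LearnerSpec]:
    """Small fixed-size learners for fast structural tests of the cascade."""
    return [
        LearnerSpec(
            name="random_forest",
            factory=lambda seed: RandomForestClassifier(random_state=seed),
            space={"clf__n_estimators": [30], "clf__max_features": ["sqrt"]},
            n_iter=1,
        ),
        LearnerSpec(
            name="gradient_boosting",
            factory=lambda seed: GradientBoostingClassifier(random_state=seed),
            space={"clf__n_estimators": [30], "clf__max_depth": [2]},
            n_iter=1,
        ),
        LearnerSpec(
            name="logistic",
            factory=lambda seed: LogisticRegression(max_iter=500),
            space={"clf__C": [1.0]},
            n_iter=1,
        ),
    ]
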