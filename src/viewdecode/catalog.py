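"""Stimulus catalog: object sets of 4 deformed objects x 4 viewing angles.

Each object set holds four similar objects (daughters of one prototype),
each rendered at viewing angles 0, 30, 60 and 90 deg, i.e. 16 images per
set.  A set carries the prior-experience condition under which the animal
encountered its images: ``object_task`` (different views of one object
shown in sequence, inducing view association) or ``across_set_task``
(images merely experienced, no view association).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

VIEW_ANGLES: tuple[int, ...] = (0, 30, 60, 90)
OBJECT_IDS: tuple[int, ...] = (1, 2, 3, 4)
EXPERIENCES: tuple[str, str] = ("object_task", "across_set_task")
IMAGES_PER_SET: int = len(OBJECT_IDS) * len(VIEW_ANGLES)

CATALOG_COLUMNS = ["set_id", "object_id", "view_angle_deg", "experience"]


def _default_set_ids(n_sets: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n_sets)]


def generate_catalog(
    n_sets: int,
    experience_assignment: Mapping[str, str] | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a stimulus catalog of ``n_sets`` object sets.

    Parameters
    ----------
    n_sets
        Number of object sets; each contributes exactly 16 images
        (4 objects x 4 views at 30 deg steps).
    experience_assignment
        Experience condition per set: either a mapping ``set_id ->
        experience`` covering every set exactly once, or a sequence of
        experiences (one per set, sets named ``"A", "B", ...``).  Default
        alternates ``object_task`` / ``across_set_task``.

    Returns
    -------
    DataFrame with columns ``set_id, object_id, view_angle_deg, experience``
    and one row per image.
    """
    if n_sets < 1:
        raise ValueError(f"n_sets must be >= 1, got {n_sets}")

    if experience_assignment is None:
        set_ids = _default_set_ids(n_sets)
        assignment = {s: EXPERIENCES[i % 2] for i, s in enumerate(set_ids)}
    elif isinstance(experience_assignment, Mapping):
        assignment = dict(experience_assignment)
        if len(assignment) != n_sets:
            raise ValueError(
                f"experience_assignment maps {len(assignment)} sets, expected {n_sets}"
            )
    else:
        exps = list(experience_assignment)
        if len(exps) != n_sets:
            raise ValueError(
                f"experience_assignment lists {len(exps)} experiences, expected {n_sets}"
            )
        assignment = dict(zip(_default_set_ids(n_sets), exps))

    for set_id, exp in assignment.items():
        if exp not in EXPERIENCES:
            raise ValueError(
                f"set {set_id!r} mapped to unknown experience {exp!r}; "
                f"expected one of {EXPERIENCES}"
            )

    rows = [
        (set_id, obj, angle, assignment[set_id])
        for set_id in assignment
        for obj in OBJECT_IDS
        for angle in VIEW_ANGLES
    ]
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)
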