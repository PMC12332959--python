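"""Documented simulation presets.

``paper_roster_config`` reproduces the recorded-population bookkeeping:
per-condition responsive-cell counts of 60 (TE/object task), 49 (TE/
across-set task), 40 (TEO/object task) and 65 (TEO/across-set task),
summing to the 109 TE and 105 TEO analysis cells.  Association strength
is high for the TE/object-task group (view-association experience drives
view-invariant object tuning), intermediate for TE/across-set, and low
for both TEO groups (predominantly view-specific tuning).

``contrast_config`` is the two-population qualitative-contrast preset:
an association-rich TE-like group against an association-poor TEO-like
group, 64 cells each, used to reproduce the headline result (TE-like
populations generalize across 30-90 deg; TEO-like across 30 deg only).

``zero_signal_config`` removes all evoked tuning (gain scale 0) for
type-I-error checks of the full decode + significance chain.
"""

from __future__ import annotations

from .simulate import GroupSpec, SimConfig

# responsive-cell counts per (area, experience) condition
PAPER_ROSTERS: dict[tuple[str, str], int] = {
    ("TE", "object_task"): 60,
    ("TE", "across_set_task"): 49,
    ("TEO", "object_task"): 40,
    ("TEO", "across_set_task"): 65,
}

# group-mean association strengths (package choices, see docs/methods.md)
ALPHA_MEANS: dict[tuple[str, str], float] = {
    ("TE", "object_task"): 0.75,
    ("TE", "across_set_task"): 0.30,
    ("TEO", "object_task"): 0.10,
    ("TEO", "across_set_task"): 0.10,
}


def paper_roster_config(seed: int = 0, n_trials_per_image: int = 20) -> SimConfig:
    """Four cell groups with the recorded per-condition roster sizes."""
    groups = [
        GroupSpec(area=a, experience=e, n_cells=n, alpha_mean=ALPHA_MEANS[(a, e)])
        for (a, e), n in PAPER_ROSTERS.items()
    ]
    return SimConfig(
        groups=groups,
        n_sets=2,
        set_experiences=["object_task", "across_set_task"],
        n_trials_per_image=n_trials_per_image,
        rng_seed=seed,
    )


def contrast_config(
    seed: int = 0,
    n_cells: int = 64,
    n_trials_per_image: int = 20,
    alpha_high: float = 0.75,
    alpha_low: float = 0.10,
) -> SimConfig:
    """Two-population preset: association-rich TE-like vs poor TEO-like."""
    groups = [
        GroupSpec(area="TE", experience="object_task", n_cells=n_cells, alpha_mean=alpha_high),
        GroupSpec(area="TEO", experience="object_task", n_cells=n_cells, alpha_mean=alpha_low, alpha_concentration=30.0),
    ]
    return SimConfig(
        groups=groups,
        n_sets=1,
        set_experiences=["object_task"],
        n_trials_per_image=n_trials_per_image,
        rng_seed=seed,
    )


def zero_signal_config(
    seed: int = 0, n_cells: int = 24, n_trials_per_image: int = 10
) -> SimConfig:
    """No evoked tuning anywhere: spikes are pure baseline Poisson trains."""
    groups = [
        GroupSpec(area="TE", experience="object_task", n_cells=n_cells, alpha_mean=0.5)
    ]
    return SimConfig(
        groups=groups,
        n_sets=1,
        set_experiences=["object_task"],
        n_trials_per_image=n_trials_per_image,
        rng_seed=seed,
        tuning_gain_scale=0.0,
    )


PRESETS = {
    "paper": paper_roster_config,
    "contrast": contrast_config,
    "zero_signal": zero_signal_config,
}
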