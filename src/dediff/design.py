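"""Experimental design: stimulus hierarchy, study lists, trial sequencing.

Eight pictures form a 2 (category) x 2 (subcategory) x 2 (exemplar)
hierarchy.  192 trial-unique adjectives are paired with the pictures and
split into three balanced 64-item study lists; at test half of each list is
shown intact and half recombined (the adjective re-paired with a different
picture studied in the same list).  Trial orders are drawn by rejection
sampling under run-length constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: category -> subcategory -> (exemplar, exemplar)
HIERARCHY_SPEC: dict[str, dict[str, tuple[str, str]]] = {
    "object": {
        "living": ("rabbit", "butterfly"),
        "inanimate": ("umbrella", "teapot"),
    },
    "scene": {
        "indoor": ("office", "bedroom"),
        "outdoor": ("beach", "forest"),
    },
}

RELATEDNESS_LEVELS = ("SE", "SS", "SC", "DC")

TRIAL_DURATION_S = 5.0
ITI_S = 1.0
SOA_S = TRIAL_DURATION_S + ITI_S

EVENT_COLUMNS = [
    "onset", "duration", "trial_type", "stimulus", "subcategory", "category",
    "status", "response", "outcome",
]


@dataclass(frozen=True)
class StimulusHierarchy:
    """The fixed 2x2x2 picture structure."""

    exemplars: tuple[str, ...]
    subcategory_of: dict[str, str]
    category_of: dict[str, str]

    def __post_init__(self):
        if len(self.exemplars) != 8 or len(set(self.exemplars)) != 8:
            raise ValueError("hierarchy requires exactly 8 unique exemplars")

    def category(self, exemplar: str) -> str:
        self._check(exemplar)
        return self.category_of[exemplar]

    def subcategory(self, exemplar: str) -> str:
        self._check(exemplar)
        return self.subcategory_of[exemplar]

    def _check(self, exemplar: str) -> None:
        if exemplar not in self.category_of:
            raise KeyError(f"unknown exemplar {exemplar!r}")


@dataclass(frozen=True)
class PairedAssociate:
    """One adjective-picture pair with its test-phase fate."""

    adjective: str
    picture: str
    list_index: int  # 1-based
    test_status: str  # "intact" | "recombined"
    recombined_picture: str | None = None

    @property
    def test_picture(self) -> str:
        """Picture (word label) actually shown at test."""
        if self.test_status == "recombined":
            assert self.recombined_picture is not None
            return self.recombined_picture
        return self.picture


def build_hierarchy() -> StimulusHierarchy:
    """Return the fixed 8-picture hierarchy (4 objects, 4 scenes)."""
    exemplars: list[str] = []
    sub_of: dict[str, str] = {}
    cat_of: dict[str, str] = {}
    for cat, subs in HIERARCHY_SPEC.items():
        for sub, exs in subs.items():
            for ex in exs:
                exemplars.append(ex)
                sub_of[ex] = sub
                cat_of[ex] = cat
    return StimulusHierarchy(tuple(exemplars), sub_of, cat_of)


def relatedness_level(hierarchy: StimulusHierarchy, a: str, b: str) -> str:
    """Relatedness of two exemplars: SE, SS, SC or DC.

    SE: same exemplar; SS: same subcategory, different exemplar; SC: same
    category, different subcategory; DC: different category.
    """
    hierarchy._check(a)
    hierarchy._check(b)
    if a == b:
        return "SE"
    if hierarchy.subcategory_of[a] == hierarchy.subcategory_of[b]:
        return "SS"
    if hierarchy.category_of[a] == hierarchy.category_of[b]:
        return "SC"
    return "DC"


def _derangement(items: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Random fixed-point-free permutation, as a mapping."""
    items = list(items)
    while True:
        perm = rng.permutation(len(items))
        if not np.any(perm == np.arange(len(items))):
            return {items[i]: items[int(p)] for i, p in enumerate(perm)}


def make_lists(
    hierarchy: StimulusHierarchy,
    n_pairs: int = 192,
    n_lists: int = 3,
    seed: int | np.random.Generator = 0,
    version: int = 0,
) -> list[list[PairedAssociate]]:
    """Build ``n_lists`` balanced study lists of paired associates.

    Each list holds ``n_pairs / n_lists`` pairs with an equal count per
    picture.  Half of each list is flagged intact and half recombined;
    recombined pairs are re-paired by a picture derangement so that no
    adjective keeps its studied picture and the per-picture balance is
    preserved at test.  ``version`` (0 or 1) selects the counterbalance
    assignment: version 1 swaps the intact/recombined flags of version 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pictures = list(hierarchy.exemplars)
    if n_pairs % n_lists != 0:
        raise ValueError(f"n_pairs={n_pairs} not divisible by n_lists={n_lists}")
    per_list = n_pairs // n_lists
    if per_list % len(pictures) != 0:
        raise ValueError(
            f"per-list count {per_list} not divisible by {len(pictures)} pictures"
        )
    per_pic = per_list // len(pictures)
    if version not in (0, 1):
        raise ValueError("version must be 0 or 1")

    adjectives = [f"adj_{i + 1:04d}" for i in range(n_pairs)]
    lists: list[list[PairedAssociate]] = []
    adj_iter = iter(adjectives)
    for li in range(n_lists):
        pics = np.array(pictures * per_pic)
        rng.shuffle(pics)
        # intact/recombined split, balanced per picture when possible
        base_flags: dict[str, list[bool]] = {}
        for pic in pictures:
            k = per_pic // 2
            flags = [True] * k + [False] * (per_pic - k)
            rng.shuffle(flags)
            base_flags[pic] = flags
        if per_pic % 2 == 1:
            # degenerate sizes: each picture has one excess recombined flag;
            # flip half of them so the list splits 50/50 overall
            for pic in rng.permutation(pictures)[: len(pictures) // 2]:
                flags = base_flags[pic]
                flags[flags.index(False)] = True
        taken = {pic: 0 for pic in pictures}
        pairs: list[PairedAssociate] = []
        for pic in pics:
            intact = base_flags[pic][taken[pic]]
            taken[pic] += 1
            if version == 1:
                intact = not intact
            pairs.append(
                PairedAssociate(
                    adjective=next(adj_iter),
                    picture=str(pic),
                    list_index=li + 1,
                    test_status="intact" if intact else "recombined",
                )
            )
        # re-pair recombined adjectives via a derangement of the pictures
        sigma = _derangement(pictures, rng)
        pairs = [
            replace(p, recombined_picture=sigma[p.picture])
            if p.test_status == "recombined" else p
            for p in pairs
        ]
        lists.append(pairs)
    return lists


# --- trial sequencing -------------------------------------------------------

MAX_SAME_CATEGORY_RUN = 4
MAX_SAME_IMAGE_RUN = 2
MAX_SAME_STATUS_RUN = 4


def _max_run_length(codes: np.ndarray) -> int:
    if codes.size == 0:
        return 0
    boundaries = np.flatnonzero(np.diff(codes) != 0)
    edges = np.concatenate(([-1], boundaries, [codes.size - 1]))
    return int(np.max(np.diff(edges)))


def order_is_valid(
    categories: np.ndarray, images: np.ndarray, statuses: np.ndarray | None = None
) -> bool:
    """Check the run-length constraints on a candidate trial order."""
    if _max_run_length(categories) > MAX_SAME_CATEGORY_RUN:
        return False
    if _max_run_length(images) > MAX_SAME_IMAGE_RUN:
        return False
    if statuses is not None and _max_run_length(statuses) > MAX_SAME_STATUS_RUN:
        return False
    return True


def sequence_trials(
    trials: list[PairedAssociate],
    phase: str,
    hierarchy: StimulusHierarchy,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 10_000,
) -> list[PairedAssociate]:
    """Order one run's trials by rejection sampling (full reshuffle on any
    violation), under: <=4 consecutive same-category images, <=2 consecutive
    presentations of the same image, and (test phase only) <=4 consecutive
    same test-status trials.
    """
    if phase not in ("study", "test"):
        raise ValueError(f"unknown phase {phase!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(trials)
    shown = [t.picture if phase == "study" else t.test_picture for t in trials]
    img_codes = pd.Categorical(shown).codes.astype(np.int64)
    cat_codes = pd.Categorical(
        [hierarchy.category_of[s] for s in shown]
    ).codes.astype(np.int64)
    status_codes = None
    if phase == "test":
        status_codes = pd.Categorical([t.test_status for t in trials]).codes.astype(np.int64)
    for _attempt in range(max_attempts):
        perm = rng.permutation(n)
        ok = order_is_valid(
            cat_codes[perm],
            img_codes[perm],
            None if status_codes is None else status_codes[perm],
        )
        if ok:
            return [trials[int(i)] for i in perm]
    raise RuntimeError(
        f"no valid {phase} order found in {max_attempts} attempts for {n} trials"
    )


# --- event tables -----------------------------------------------------------

def make_run_events(
    ordered: list[PairedAssociate],
    phase: str,
    run: int,
    hierarchy: StimulusHierarchy,
) -> pd.DataFrame:
    """Event table for one run: fixed 5 s trials at a 6 s SOA."""
    rows = []
    for i, t in enumerate(ordered):
        pic = t.picture if phase == "study" else t.test_picture
        rows.append(
            {
                "onset": i * SOA_S,
                "duration": TRIAL_DURATION_S,
                "trial_type": phase,
                "stimulus": pic,
                "subcategory": hierarchy.subcategory_of[pic],
                "category": hierarchy.category_of[pic],
                "status": t.test_status,
                "response": "n/a",
                "outcome": "n/a",
                "adjective": t.adjective,
                "studied_picture": t.picture,
                "run": run,
                "trial_index": i,
            }
        )
    df = pd.DataFrame(rows)
    if not np.all(np.diff(df["onset"]) > 0):
        raise AssertionError("onsets must be strictly increasing")
    return df


def make_localizer_events(
    hierarchy: StimulusHierarchy,
    n_reps: int = 12,
    duration_s: float = 4.0,
    isi_s: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Localizer run: every picture shown ``n_reps`` times (8 x 12 = 96
    events by default), 4 s on / 1 s off, order constrained like a study run.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stims = np.array(list(hierarchy.exemplars) * n_reps)
    cat = pd.Categorical([hierarchy.category_of[s] for s in stims]).codes.astype(np.int64)
    img = pd.Categorical(stims).codes.astype(np.int64)
    for _ in range(10_000):
        perm = rng.permutation(stims.size)
        if order_is_valid(cat[perm], img[perm]):
            break
    else:  # pragma: no cover
        raise RuntimeError("no valid localizer order found")
    stims = stims[perm]
    soa = duration_s + isi_s
    return pd.DataFrame(
        {
            "onset": np.arange(stims.size) * soa,
            "duration": duration_s,
            "trial_type": "localizer",
            "stimulus": stims,
            "subcategory": [hierarchy.subcategory_of[s] for s in stims],
            "category": [hierarchy.category_of[s] for s in stims],
            "status": "n/a",
            "response": "n/a",
            "outcome": "n/a",
            "run": 0,
            "trial_index": np.arange(stims.size),
        }
    )


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    """Write an events table as tab-separated text (BIDS events dialect)."""
    cols = EVENT_COLUMNS + [c for c in events.columns if c not in EVENT_COLUMNS]
    events.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
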