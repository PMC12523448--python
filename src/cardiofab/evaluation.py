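"""Dice evaluation and the ablation/comparison harness.

The Dice similarity coefficient between a ground-truth mask G and a
prediction P is 2|G∩P| / (|G| + |P|), in [0, 1] with 1 for a perfect
match.  Conventions for degenerate cases (fixed here for stable
averages): both masks empty -> 1.0; exactly one empty -> 0.0.

The ablation harness trains the four study arms — single-stage
baseline, two-stage cascade, cascade + anatomical prior, and cascade +
prior + co-attention — on a shared phantom split over several seeds and
tabulates per-structure Dice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import SMALL_CODES, SUBSTRUCTURES, substructure
from .phantom import LabeledVolume
from .segmentation import (CascadeModel, NetConfig, TrainConfig, predict,
                           predict_cascade, train, train_cascade)

__all__ = ["MaskPair", "DiceReport", "dice", "evaluate_cases",
           "ABLATION_ARMS", "run_arm", "ablation_study"]


@dataclass(frozen=True)
class MaskPair:
    """A ground-truth / prediction binary mask pair on one grid."""

    G: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        if self.G.shape != self.P.shape:
            raise ValueError(f"shape mismatch {self.G.shape} vs {self.P.shape}")
        for name, m in (("G", self.G), ("P", self.P)):
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} is not binary")


def dice(pair_or_g, p=None) -> float:
    """Dice similarity coefficient of a mask pair.

    Accepts a :class:`MaskPair` or two binary arrays.  Symmetric; both
    masks empty gives 1.0, disjoint nonempty masks give 0.0.
    """
    pair = pair_or_g if isinstance(pair_or_g, MaskPair) else MaskPair(
        np.asarray(pair_or_g), np.asarray(p))
    g = pair.G.astype(bool)
    pr = pair.P.astype(bool)
    total = int(g.sum()) + int(pr.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((g & pr).sum()) / total


@dataclass
class DiceReport:
    """Per-substructure Dice averaged over cases, plus the macro mean."""

    per_structure: dict[str, float]
    macro_average: float
    case_count: int
    per_case: pd.DataFrame = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"structure": k, "dice": v} for k, v in self.per_structure.items()]
        rows.append({"structure": "macro_average", "dice": self.macro_average})
        return pd.DataFrame(rows)


def _labels_of(obj) -> np.ndarray:
    if isinstance(obj, LabeledVolume):
        return obj.labels
    if hasattr(obj, "labels"):
        return obj.labels
    return np.asarray(obj)


def evaluate_cases(predictions: list, truths: list,
                   case_ids: list[str] | None = None) -> DiceReport:
    """Dice per substructure, averaged over matched prediction/truth cases.

    ``predictions``/``truths`` may be Prediction objects, LabeledVolumes
    or plain label arrays with global codes.  A structure absent from
    both maps of a case scores 1.0 for that case, absent from exactly
    one scores 0.0.
    """
    if len(predictions) != len(truths):
        raise ValueError("prediction and truth case lists differ in length")
    if case_ids is not None and len(case_ids) != len(predictions):
        raise ValueError("case id list does not match the case count")
    rows = []
    for i, (pred, truth) in enumerate(zip(predictions, truths)):
        pl, tl = _labels_of(pred), _labels_of(truth)
        if pl.shape != tl.shape:
            cid = case_ids[i] if case_ids else i
            raise ValueError(f"case {cid}: prediction/truth grids differ")
        row = {"case": case_ids[i] if case_ids else f"case{i}"}
        for s in SUBSTRUCTURES:
            row[s.abbrev] = dice(tl == s.code, pl == s.code)
        rows.append(row)
    per_case = pd.DataFrame(rows).set_index("case")
    per_structure = {s.abbrev: float(per_case[s.abbrev].mean()) for s in SUBSTRUCTURES}
    macro = float(np.mean(list(per_structure.values())))
    return DiceReport(per_structure=per_structure, macro_average=macro,
                      case_count=len(rows), per_case=per_case)


#: The four study arms, in increasing order of machinery.
ABLATION_ARMS = ("baseline", "two_stage", "prior", "prior_attention")


def run_arm(arm: str, train_cases: list[LabeledVolume],
            test_cases: list[LabeledVolume], config: TrainConfig,
            depth: int = 2, ls_width: int = 8, ss_width: int = 6,
            coarse_factor: int = 2, _ls_cache: dict | None = None) -> DiceReport:
    """Train one ablation arm and evaluate it on the test cases.

    The single-stage baseline is a full-resolution 11-class net with the
    fine stage's width (capacity-matched, same patch sampler); cascade
    arms pair a wider half-resolution coarse net (large structures
    only) with the full-resolution fine net, without or with prior
    fusion and co-attention.  ``_ls_cache`` lets a study reuse the
    coarse net across cascade arms of one seed — its training there is
    bit-identical, so this is pure memoization.
    """
    from .segmentation import normalize_intensity

    if arm == "baseline":
        cfg = NetConfig(1, 11, depth, ss_width, False, config.seed)
        net = cfg.build()
        codes = tuple(range(11))
        train(net, train_cases, config, class_codes=codes)
        preds = [predict(net, normalize_intensity(c.intensity)[None], codes)
                 for c in test_cases]
    elif arm in ("two_stage", "prior", "prior_attention"):
        model = CascadeModel.create(
            depth=depth, ls_width=ls_width, ss_width=ss_width,
            use_prior=arm in ("prior", "prior_attention"),
            attention=arm == "prior_attention",
            coarse_factor=coarse_factor, seed=config.seed)
        cached = None if _ls_cache is None else _ls_cache.get(config.seed)
        train_cascade(model, train_cases, config, ls_net=cached)
        if _ls_cache is not None:
            _ls_cache[config.seed] = model.ls_net
        preds = [predict_cascade(model, c.intensity) for c in test_cases]
    else:
        raise ValueError(f"unknown ablation arm {arm!r}")
    return evaluate_cases(preds, test_cases)


def ablation_study(arms: list[str], train_cases: list[LabeledVolume],
                   test_cases: list[LabeledVolume], seeds: list[int],
                   config: TrainConfig | None = None,
                   **arm_kwargs) -> pd.DataFrame:
    """Per-structure Dice (mean ± SD over seeds) for each configuration.

    All arms share the same phantom split and the same seed list, so
    rows are directly comparable.  Returns a tidy frame with one row per
    (configuration, structure).
    """
    if len(arms) < 1:
        raise ValueError("need at least one configuration")
    config = config or TrainConfig()
    import dataclasses as _dc

    records = []
    ls_cache: dict = {}
    for arm in arms:
        per_seed = []
        for seed in seeds:
            rep = run_arm(arm, train_cases, test_cases,
                          _dc.replace(config, seed=seed),
                          _ls_cache=ls_cache, **arm_kwargs)
            per_seed.append(rep)
        for s in SUBSTRUCTURES:
            vals = [r.per_structure[s.abbrev] for r in per_seed]
            records.append({
                "config": arm, "structure": s.abbrev,
                "size_class": s.size_class,
                "dice_mean": float(np.mean(vals)),
                "dice_sd": float(np.std(vals)),
                "seeds": len(seeds),
            })
        small = [np.mean([r.per_structure[substructure(c).abbrev]
                          for c in SMALL_CODES]) for r in per_seed]
        records.append({
            "config": arm, "structure": "small_group_mean",
            "size_class": "small",
            "dice_mean": float(np.mean(small)),
            "dice_sd": float(np.std(small)),
            "seeds": len(seeds),
        })
    return pd.DataFrame.from_records(records)
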