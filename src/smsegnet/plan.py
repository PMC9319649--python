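"""Constrained enumeration of the channel plan against a parameter budget.

The per-level fire-module widths of the reference network are not free
choices: they are solved so that the full model's trainable-parameter total
reproduces the published budget exactly.  The search space is constrained to
plans with

* two fire modules per level sharing widths, with equal 1x1 and 3x3 expand
  branches (e1 == e3),
* expand widths doubling per encoder level from a base width, the decoder
  mirroring them one level shifted (an unpooling constraint: every decoder
  block must emit the channel count its pooling indices were recorded with),
* the bottleneck expand width pinned to the deepest encoder expand width,
* squeeze widths free per level.

The parameter total is exactly linear in each squeeze width, so for every
base width the remaining problem is a small integer linear equation; among
exact solutions the solver prefers, deterministically, the plan whose squeeze
widths deviate least (L1) from the SqueezeNet-style ratio squeeze = expand/2,
breaking ties by smaller base width and lexicographic deltas.
"""

from __future__ import annotations

import numpy as np

from .config import ChannelPlan, SMSegNetConfig

__all__ = ["solve_channel_plan", "REFERENCE_PARAMETER_TOTAL"]

#: Published trainable-parameter total of the combined reference model.
REFERENCE_PARAMETER_TOTAL = 835_776


def _total(base: int, squeeze: list[int], sb: int, levels: int,
           num_classes: int, input_size) -> int:
    plan = ChannelPlan(
        encoder_expand=tuple(base * 2 ** i for i in range(levels)),
        encoder_squeeze=tuple(squeeze),
        bottleneck_expand=base * 2 ** (levels - 1),
        bottleneck_squeeze=sb,
    )
    cfg = SMSegNetConfig(plan=plan, num_classes=num_classes,
                         input_size=input_size)
    return cfg.layout().n_parameters


def solve_channel_plan(
    target_total: int = REFERENCE_PARAMETER_TOTAL,
    levels: int = 4,
    num_classes: int = 4,
    input_size: tuple[int, int, int] = (128, 128, 1),
    base_widths: tuple[int, ...] = (4, 6, 8, 12, 16, 20, 24, 32, 40, 48),
    delta_max: int = 48,
) -> SMSegNetConfig:
    """Solve the squeeze/expand widths for an exact parameter total.

    Returns the configuration of the best exact solution found, or raises
    ``ValueError`` if no candidate base width admits one.
    """
    best = None  # (dev, base, deltas) -> canonical ordering
    for base in sorted(base_widths):
        expand = [base * 2 ** i for i in range(levels)]
        s0 = [max(1, e // 2) for e in expand]
        sb0 = max(1, expand[-1] // 2)

        def total(sq, sb):
            return _total(base, sq, sb, levels, num_classes, input_size)

        base_total = total(s0, sb0)
        coef = []
        for i in range(levels):
            bumped = list(s0)
            bumped[i] += 1
            coef.append(total(bumped, sb0) - base_total)
        coef_b = total(s0, sb0 + 1) - base_total
        need = target_total - base_total

        # The total is linear in the squeeze widths; enumerate integer
        # deltas (vectorized over the first levels) and solve the last one.
        # Once an exact solution exists, its L1 deviation bounds every
        # per-level delta of any better solution, which prunes the search.
        bound = delta_max if best is None else min(delta_max, best[0])
        ranges = [np.arange(max(-(s - 1), -bound), bound + 1) for s in s0]
        grids = np.meshgrid(*ranges[:-1], indexing="ij")
        rem = need - sum(c * g for c, g in zip(coef[:-1], grids))
        partial_dev = sum(np.abs(g) for g in grids)
        for d_last in ranges[-1]:
            rem2 = rem - coef[-1] * int(d_last)
            db, mod = np.divmod(rem2, coef_b)
            ok = (mod == 0) & (db > -sb0) & (np.abs(db) <= bound)
            if not ok.any():
                continue
            dev = partial_dev + abs(int(d_last)) + np.abs(db)
            dev = np.where(ok, dev, np.iinfo(np.int64).max)
            flat = int(dev.argmin())
            at = np.unravel_index(flat, dev.shape)
            deltas = tuple(int(g[at]) for g in grids) + (int(d_last), int(db[at]))
            cand = (int(dev[at]), base, deltas)
            if best is None or cand < best:
                best = cand
                bound = min(delta_max, best[0])
    if best is None:
        raise ValueError(
            f"no channel plan with the given constraints reaches a total of "
            f"{target_total} parameters")

    _, base, deltas = best
    expand = tuple(base * 2 ** i for i in range(levels))
    squeeze = tuple(e // 2 + d for e, d in zip(expand, deltas[:levels]))
    sb = expand[-1] // 2 + deltas[-1]
    plan = ChannelPlan(encoder_expand=expand, encoder_squeeze=squeeze,
                       bottleneck_expand=expand[-1], bottleneck_squeeze=sb)
    cfg = SMSegNetConfig(plan=plan, num_classes=num_classes,
                         input_size=input_size)
    total = cfg.layout().n_parameters
    if total != target_total:
        raise AssertionError(
            f"solver produced an inexact plan: {total} != {target_total}")
    return cfg
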