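"""Pseudo individual patient data from digitized Kaplan-Meier curves.

Published trial figures give a KM step function plus a number-at-risk table;
the Guyot-style procedure implemented here inverts the product-limit
estimator interval by interval to recover per-patient (time, event) records
whose KM estimate tracks the digitized curve and whose at-risk counts match
the published table exactly.

The reconstruction is fully deterministic: censoring times are placed at
equally spaced points within each risk interval, and event counts are
rounded with a remainder-carrying scheme so interval totals are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "PseudoIPD",
    "sanitize_curve",
    "reconstruct_ipd",
    "km_estimate",
    "ReconstructionError",
]


class ReconstructionError(RuntimeError):
    """Digitized inputs are mutually inconsistent."""


@dataclass
class DigitizedCurve:
    """Step-function survival coordinates extracted from a published figure."""

    time: np.ndarray
    survival: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.time.size == 0:
            raise ValueError("DigitizedCurve needs at least one point")
        if self.time.shape != self.survival.shape:
            raise ValueError("time and survival must have equal length")

    def value_at(self, t) -> np.ndarray:
        """Right-continuous step interpolation; 1.0 before the first point."""
        idx = np.searchsorted(self.time, np.asarray(t, dtype=float), side="right") - 1
        return np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "survival": self.survival})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm: str = "", endpoint: str = "") -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["survival"].to_numpy(), arm, endpoint)


@dataclass
class RiskTable:
    """Number-at-risk counts printed beneath a KM figure."""

    time: np.ndarray
    n_risk: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if self.time.size == 0:
            raise ValueError("RiskTable needs at least one entry")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if self.time[0] != 0:
            raise ValueError("risk table must start at time 0")
        if np.any(self.n_risk < 0):
            raise ValueError("at-risk counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "n_risk": self.n_risk})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["n_risk"].to_numpy())


@dataclass
class PseudoIPD:
    """Reconstructed per-patient (time, event) records."""

    time: np.ndarray
    event: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "event": self.event})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "") -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy(), provenance)


def sanitize_curve(raw: DigitizedCurve) -> DigitizedCurve:
    """Clean digitization noise: clamp to [0,1], enforce a nonincreasing
    step function via running minimum, deduplicate equal times keeping the
    last reading, and prepend the (0, 1) origin if absent. Idempotent."""
    if np.any(raw.time < 0):
        raise ValueError("digitized times must be nonnegative")
    order = np.argsort(raw.time, kind="stable")
    t, s = raw.time[order], np.clip(raw.survival[order], 0.0, 1.0)
    # keep last reading at duplicated times
    keep = np.r_[t[1:] != t[:-1], True]
    t, s = t[keep], s[keep]
    if t[0] != 0.0:
        t, s = np.r_[0.0, t], np.r_[1.0, s]
    else:
        s[0] = 1.0  # the origin is definitionally S(0) = 1
    s = np.minimum.accumulate(s)
    return DigitizedCurve(t, s, raw.arm, raw.endpoint)


def _walk_interval(steps_t, steps_s, n_in, s_in, censor_times, t_hi):
    """Walk digitized steps within one risk interval for a trial censor count.

    Returns (event counts per step, at-risk count at t_hi, KM value after the
    interval). Censorings are removed before the first later event step (tie
    convention: events first at equal times).
    """
    n_hat = n_in
    s_hat = s_in
    carry = 0.0
    d_out = []
    c_idx = 0
    nc = len(censor_times)
    for tk, sk in zip(steps_t, steps_s):
        while c_idx < nc and censor_times[c_idx] < tk:
            n_hat -= 1
            c_idx += 1
        if sk < s_hat - 1e-12 and n_hat <= 0:
            raise ReconstructionError(
                f"survival drops at t={tk} with nobody left at risk"
            )
        if n_hat > 0 and s_hat > 0:
            d_real = n_hat * (1.0 - sk / s_hat)
        else:
            d_real = 0.0
        d = int(round(d_real + carry))
        d = max(0, min(d, n_hat))
        carry += d_real - d
        if d > 0:
            s_hat *= 1.0 - d / n_hat
            n_hat -= d
        d_out.append(d)
    n_hat -= nc - c_idx  # censorings after the last step, before t_hi
    return d_out, n_hat, s_hat


def _replay_interval(steps_t, d_fixed, n_in, s_in, censor_times):
    """Recompute (at-risk, KM value) at interval end for fixed event counts."""
    n_hat, s_hat = n_in, s_in
    ct = sorted(censor_times)
    ci = 0
    for tk, d in zip(steps_t, d_fixed):
        while ci < len(ct) and ct[ci] < tk:
            n_hat -= 1
            ci += 1
        if d > 0 and n_hat > 0:
            s_hat *= 1.0 - d / n_hat
            n_hat -= d
    n_hat -= len(ct) - ci
    return n_hat, s_hat


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable,
    total_events: int | None = None,
    max_iter: int = 10_000,
) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized curve and its risk table.

    For each risk interval the censor count is iterated (equally spaced
    censoring times, integer event counts from the product-limit relation)
    until the implied number at risk at the next published time matches the
    published count exactly. After the last risk entry no censoring is
    assumed unless ``total_events`` is given, in which case residual events
    and censorings at the curve end are balanced to match it.
    """
    curve = sanitize_curve(curve)
    if np.any(np.diff(risk.n_risk) > 0):
        raise ReconstructionError("at-risk counts increase along the risk table")
    t_d, s_d = curve.time, curve.survival
    R, N = risk.time, risk.n_risk
    n0 = int(N[0])
    if n0 <= 0:
        raise ReconstructionError("initial at-risk count must be positive")

    event_times: list[float] = []
    event_counts: list[int] = []
    censor_list: list[float] = []

    n_hat, s_hat = n0, 1.0
    t_end = max(float(t_d[-1]), float(R[-1]))

    for i in range(len(R) - 1):
        t_lo, t_hi = float(R[i]), float(R[i + 1])
        target = int(N[i + 1])
        mask = (t_d >= t_lo) & (t_d < t_hi) & (t_d > 0)
        steps_t, steps_s = t_d[mask], s_d[mask]

        s_lo = float(curve.value_at(t_lo))
        s_hi = float(curve.value_at(t_hi))
        nc = int(round(n_hat * (s_hi / s_lo) - target)) if s_lo > 0 else n_hat - target
        nc = max(0, min(nc, n_hat))

        def _censor_times(count: int) -> list[float]:
            return [t_lo + (j + 1) / (count + 1) * (t_hi - t_lo) for j in range(count)]

        tried: set[int] = set()
        best = None  # (|residual|, nc, d_out, ct, n_end, s_end)
        solved = False
        for _ in range(max_iter):
            ct = _censor_times(nc)
            d_out, n_end, s_end = _walk_interval(steps_t, steps_s, n_hat, s_hat, ct, t_hi)
            resid = n_end - target
            if best is None or abs(resid) < best[0]:
                best = (abs(resid), nc, d_out, ct, n_end, s_end)
            if resid == 0:
                solved = True
                break
            tried.add(nc)
            nc_new = max(0, min(nc + resid, n_hat))
            if nc_new in tried:
                break  # integer rounding leaves a residue; force-fix below
            nc = nc_new
        if not solved:
            # no censor count matches exactly (event rounding residue):
            # take the closest allocation and rebalance its tail
            _, nc, d_out, ct, n_end, s_end = best
            resid = n_end - target
            if resid > 0:
                # censor the surplus between the last event and the interval end
                t_ref = max([t_lo] + steps_t.tolist())
                ct = ct + list(np.linspace(t_ref, t_hi, resid + 2)[1:-1])
            else:
                need = -resid
                for k in range(len(d_out) - 1, -1, -1):  # retract latest events
                    take = min(d_out[k], need)
                    d_out[k] -= take
                    need -= take
                    if need == 0:
                        break
                if need > 0:  # then drop censorings
                    drop = min(len(ct), need)
                    ct = ct[: len(ct) - drop]
                    need -= drop
                if need > 0:
                    raise ReconstructionError(
                        f"inconsistent inputs in interval {i}: [{t_lo}, {t_hi}) — "
                        f"published at-risk count {target} is unreachable"
                    )
            n_end, s_end = _replay_interval(steps_t, d_out, n_hat, s_hat, ct)
            if n_end != target:
                raise ReconstructionError(
                    f"cannot match published at-risk count {target} at "
                    f"t={t_hi} (interval {i}: [{t_lo}, {t_hi}))"
                )
        event_times.extend(steps_t.tolist())
        event_counts.extend(d_out)
        censor_list.extend(ct)
        n_hat, s_hat = n_end, s_end

    # tail after the last published risk time: no censoring assumed
    mask = (t_d >= R[-1]) & (t_d > 0)
    d_out, n_hat, s_hat = _walk_interval(t_d[mask], s_d[mask], n_hat, s_hat, [], np.inf)
    event_times.extend(t_d[mask].tolist())
    event_counts.extend(d_out)

    if total_events is not None:
        have = int(sum(event_counts))
        delta = int(total_events) - have
        if delta > 0:
            add = min(delta, n_hat)
            event_times.append(t_end)
            event_counts.append(add)
            n_hat -= add
        elif delta < 0:
            # convert the latest reconstructed events back into censorings
            for k in range(len(event_counts) - 1, -1, -1):
                if delta == 0:
                    break
                take = min(event_counts[k], -delta)
                event_counts[k] -= take
                censor_list.extend([event_times[k]] * take)
                delta += take

    censor_list.extend([t_end] * n_hat)  # survivors censored at end of follow-up

    times = np.concatenate([
        np.repeat(event_times, event_counts) if event_times else np.empty(0),
        np.asarray(censor_list, dtype=float),
    ])
    events = np.concatenate([
        np.ones(int(sum(event_counts)), dtype=int),
        np.zeros(len(censor_list), dtype=int),
    ])
    order = np.argsort(times, kind="stable")
    ipd = PseudoIPD(times[order], events[order],
                    provenance=f"{curve.arm}/{curve.endpoint}".strip("/"))
    assert ipd.n == n0, "reconstruction lost patients"
    return ipd


def km_estimate(ipd: PseudoIPD) -> DigitizedCurve:
    """Product-limit estimate of reconstructed (or simulated) records."""
    from lifelines import KaplanMeierFitter

    if ipd.n == 0:
        raise ValueError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    if t[0] != 0.0:
        t, s = np.r_[0.0, t], np.r_[1.0, s]
    return DigitizedCurve(t, s, arm=ipd.provenance)
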