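"""Independent day-by-day reference implementation of heatwave detection.

Deliberately structured differently from the production run-scan: every day
is labelled individually with the period it belongs to, and periods are
reassembled from the labels.  Used to cross-check the run-detection code on
exhaustive and random small inputs.
"""

import pandas as pd


def day_scan_oracle(cet, threshold, extension_days, alert_days):
    """Return [(start, end, raw_start, raw_end)] by labelling each day.

    A qualifying day (alert or CET > threshold) belongs to its own run of
    consecutive qualifying days.  A non-qualifying day belongs to the
    earliest run whose raw interval, widened by ``extension_days``, covers
    it — so a day sandwiched between two runs goes to the earlier one.
    """
    dates = list(cet.index)
    alert_days = {pd.Timestamp(d) for d in alert_days}
    qual = [bool(cet.iloc[i] > threshold or dates[i] in alert_days) for i in range(len(dates))]

    # label qualifying days with run ids
    run_of = {}
    run_id = -1
    prev_qual = False
    for i, d in enumerate(dates):
        if qual[i]:
            if not prev_qual:
                run_id += 1
            run_of[d] = run_id
        prev_qual = qual[i]
    n_runs = run_id + 1
    if n_runs == 0:
        return []

    raw = []
    for r in range(n_runs):
        days = [d for d, rid in run_of.items() if rid == r]
        raw.append((min(days), max(days)))

    # every calendar day (incl. beyond the series edge) that any extension
    # could reach, assigned to the earliest covering run
    ext = pd.Timedelta(days=extension_days)
    member = {}
    lo = min(d for d, _ in raw) - ext
    hi = max(d for _, d in raw) + ext
    day = lo
    while day <= hi:
        for r, (rs, re) in enumerate(raw):
            if rs - ext <= day <= re + ext:
                member[day] = r
                break
        day += pd.Timedelta(days=1)

    out = []
    for r, (rs, re) in enumerate(raw):
        days = [d for d, rid in member.items() if rid == r]
        out.append((min(days), max(days), rs, re))
    return out
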