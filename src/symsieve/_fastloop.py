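"""Specialised exact SSA loop for single-taxon populations.

The population is reduced to six exchangeable classes:

    fp, fm -- carrier / non-carrier females
    yp, ym -- carrier / non-carrier males whose Y allele suppresses male
              transmission (matings follow the maternal rule)
    zp, zm -- carrier / non-carrier males whose Y allele permits male
              transmission (matings follow the biparental rule)

Pure-mode runs place all males in one allele class.  Event rates:
birth b0 per female (zero with no males), death (d0 + d' n) per host
divided by w for carriers, uptake e0 per non-carrier.  This is the exact
process of :mod:`symsieve.gillespie` restricted to one taxon; it exists
because protocol ensembles take ~1e7 events.
"""

from __future__ import annotations

import random

__all__ = ["run_six_class"]


def run_six_class(counts, b0: float, d0: float, dprime: float, e0: float,
                  w: float, t_max: float, sample_dt: float,
                  seed: int | None, stop_on_focal: bool = True,
                  t0: float = 0.0):
    """Run one realisation; returns (outcome, t_end, records, final_counts).

    ``records`` is a list of (t, fp, fm, yp, ym, zp, zm) rows sampled every
    ``sample_dt`` time units plus a final row at the termination time.
    """
    rng = random.Random(seed)
    rnd = rng.random
    fp, fm, yp, ym, zp, zm = (int(c) for c in counts)
    t = t0
    next_s = t0
    recs = []
    outcome = None
    inv_w = 1.0 / w
    while True:
        n = fp + fm + yp + ym + zp + zm
        if n == 0:
            outcome = "host_extinction"
            break
        npos = fp + yp + zp
        if stop_on_focal:
            if npos == 0:
                outcome = "loss"
                break
            if npos == n:
                outcome = "fixation"
                break
        nF = fp + fm
        nM = n - nF
        birth = b0 * nF if nM > 0 else 0.0
        dbase = d0 + dprime * n
        nneg = n - npos
        dcar = dbase * inv_w * npos
        dnon = dbase * nneg
        upt = e0 * nneg
        total = birth + dcar + dnon + upt
        if total <= 0.0:
            t = t_max
            outcome = "timeout"
            break
        t_next = t + rng.expovariate(total)
        while next_s <= t_next and next_s <= t_max:
            recs.append((next_s, fp, fm, yp, ym, zp, zm))
            next_s += sample_dt
        if t_next >= t_max:
            t = t_max
            outcome = "timeout"
            break
        t = t_next
        r = rnd() * total
        if r < birth:
            mother_car = rnd() * nF < fp
            rm = rnd() * nM
            if rm < yp:
                f_car, f_trans = True, False
            elif rm < yp + ym:
                f_car, f_trans = False, False
            elif rm < yp + ym + zp:
                f_car, f_trans = True, True
            else:
                f_car, f_trans = False, True
            child_car = mother_car or (f_trans and f_car)
            if rnd() < 0.5:
                if child_car:
                    fp += 1
                else:
                    fm += 1
            elif f_trans:
                if child_car:
                    zp += 1
                else:
                    zm += 1
            else:
                if child_car:
                    yp += 1
                else:
                    ym += 1
        elif r < birth + dcar:
            rr = rnd() * npos
            if rr < fp:
                fp -= 1
            elif rr < fp + yp:
                yp -= 1
            else:
                zp -= 1
        elif r < birth + dcar + dnon:
            rr = rnd() * nneg
            if rr < fm:
                fm -= 1
            elif rr < fm + ym:
                ym -= 1
            else:
                zm -= 1
        else:
            rr = rnd() * nneg
            if rr < fm:
                fm -= 1
                fp += 1
            elif rr < fm + ym:
                ym -= 1
                yp += 1
            else:
                zm -= 1
                zp += 1
    recs.append((t, fp, fm, yp, ym, zp, zm))
    return outcome, t, recs, (fp, fm, yp, ym, zp, zm)
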