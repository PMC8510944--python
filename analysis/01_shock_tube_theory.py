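#!/usr/bin/env python
"""Ideal shock-tube closure for the blast tube's operating points.

Solves the diaphragm-ratio <-> shock-Mach relation for the tube's nominal
driver settings and for the measured operating point (P4/P1 = 22.5,
Ms = 1.859), and tabulates the normal-shock jump conditions.  Writes
results/theory.json.
"""

import json
from pathlib import Path

from blasttube import gasdynamics as gd
from blasttube.blast_tube import NOMINAL_PRESSURES, effective_driver_pressure

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    p1 = 101.3e3
    out = {"p1_pa": p1, "gamma": 1.4, "temperature_k": gd.T_DEFAULT}

    Ms_op = gd.mach_from_diaphragm_ratio(22.5)
    jump = gd.normal_shock_from_mach(Ms_op)
    out["operating_point"] = {
        "p4_over_p1": 22.5,
        "Ms": Ms_op,
        "measured_Ms": 1.859,
        "relative_gap": Ms_op / 1.859 - 1,
        "p2_over_p1": jump.p_ratio,
        "post_shock_speed_m_s": jump.u2,
        "shock_speed_m_s": Ms_op * gd.air().sound_speed,
    }
    cond = gd.ShockTubeCondition(driver=gd.air(22.5 * p1))
    out["ratio_at_measured_Ms"] = gd.diaphragm_ratio_from_mach(1.859, cond)

    table = []
    for nominal in NOMINAL_PRESSURES:
        p4 = effective_driver_pressure(nominal)
        Ms = gd.mach_from_diaphragm_ratio(p4 / p1)
        table.append({"nominal_mpa": nominal / 1e6,
                      "effective_p4_mpa": p4 / 1e6,
                      "Ms": Ms,
                      "p2_over_p1": gd.normal_shock_from_mach(Ms).p_ratio})
    out["driver_settings"] = table

    OUT.mkdir(exist_ok=True)
    (OUT / "theory.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"Ideal closure: P4/P1 = 22.5 -> Ms = {Ms_op:.4f} "
          f"(measured 1.859, gap {out['operating_point']['relative_gap']:+.2%})")
    print(f"Forward relation at Ms = 1.859 -> P4/P1 = "
          f"{out['ratio_at_measured_Ms']:.2f} (printed 22.5)")
    print(f"wrote {OUT / 'theory.json'}")


if __name__ == "__main__":
    main()
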