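"""Percent days covered (PDC) and its variants on small fill schedules.

PDC is total statin days supplied divided by days of follow-up, capped at
1; a patient is adherent when PDC > 0.8. The follow-up variant drops the
first prescription's pills and starts when that supply runs out.
"""

from statinadh.outcomes import compute_pdc, coverage_pdc_oracle

# one 30-day fill, then nothing, over a year of follow-up
out = compute_pdc([(0, 30)], 365)
print(f"single fill: pdc={out.pdc:.3f} adherent={out.adherent} "
      f"first_refill={out.first_refill} followup_pdc={out.followup_pdc}")

# quarterly 90-day fills: perfectly covered
out = compute_pdc([(0, 90), (90, 90), (180, 90), (270, 90)], 360)
print(f"quarterly 90-day fills: pdc={out.pdc:.3f} adherent={out.adherent}")

# overlapping fills: the supplied-days ratio counts both, the day-coverage
# oracle (pill carry-over) agrees until supply runs past the follow-up end
fills = [(0, 30), (340, 180)]
print(f"late long fill: ratio pdc={compute_pdc(fills, 365).pdc:.3f}, "
      f"day-coverage={coverage_pdc_oracle(fills, 365):.3f}")
# the ratio counts all 210 supplied days; day-by-day coverage only the 55
# days that fall inside the follow-up window
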