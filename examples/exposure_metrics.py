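"""Exposure metrics for a single progeny-monitor record.

A typical quiescent indoor observation: radon at 229 Bq m⁻³, progeny split
into unattached (cluster) and attached (aerosol-borne) fractions. The
derived metrics are the quantities radiation-protection practice reports:
EEC, equilibrium factor F, unattached fraction f_un, potential alpha
energy and the f_un-dependent dose conversion factor.
"""

import pandas as pd

from rnaero import ProgenyRecord, derive_metrics, exposure_wlm

rec = ProgenyRecord(
    timestamp=pd.Timestamp("2021-01-01 08:00"),
    c_rn=229.0,
    c_po218_un=25.0, c_pb214_un=8.0, c_bi214_un=4.0,
    c_po218_att=110.0, c_pb214_att=95.0, c_bi214_att=80.0,
)
m = derive_metrics(rec)

print(f"EEC        = {m.eec:7.2f} Bq m^-3  (equilibrium equivalent concentration)")
print(f"EEC_un     = {m.eec_un:7.2f} Bq m^-3  (unattached part)")
print(f"F          = {m.f_factor:7.3f}          (EEC / radon activity)")
print(f"f_un       = {m.f_un:7.3f}          (unattached activity fraction)")
print(f"x_un       = {m.x_un:7.3f}          (unattached atom-number fraction)")
print(f"E_alpha    = {m.e_alpha:10.0f} MeV m^-3")
print(f"D_CF       = {m.dcf:7.2f} mSv/WLM  (= 11.35 + 43 f_un)")

# a month at this level: 730 h of the same E_alpha
wlm = exposure_wlm([m.e_alpha] * 365, 2.0)
print(f"\n730 h at this concentration = {wlm:.4f} WLM "
      f"-> {wlm * m.dcf:.3f} mSv effective dose")
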