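# Synthetic ATR FT-IR band library for developing cotton fiber cell walls.
# version 1 — amplitudes frozen after a one-time design pass (see docs/methods.md)
#
# Each band is a Gaussian in wavenumber: a(latent) * exp(-(w - center)^2 / (2 sigma^2)),
# a(latent) = a_pcw * (1 - latent) + a_scw * latent.  a_pcw is the amplitude in a
# pure primary-cell-wall (young, ~10 DPA) fiber, a_scw in a fully thickened
# secondary-cell-wall fiber; the sign of (a_scw - a_pcw) encodes the observed
# increase/decrease of each band with development.
#
# group selects the driving latent in the two-latent ("realistic") mode:
#   composition — saturating PCW->SCW composition latent g (logistic in DPA)
#   maturation  — linear cellulose-maturation latent m (ramp in DPA)
# In single-latent mode every band follows the one cellulose latent.
version: 1
bands:
  - {name: oh_stretch_3330,    center: 3330.0, sigma: 95.0, a_pcw: 0.450, a_scw: 0.650, group: composition, direction: increase}
  - {name: ch_stretch_2900,    center: 2900.0, sigma: 45.0, a_pcw: 0.180, a_scw: 0.280, group: composition, direction: increase}
  - {name: carbonyl_1740,      center: 1740.0, sigma: 5.0,  a_pcw: 0.120, a_scw: 0.030, group: composition, direction: decrease}
  - {name: water_amide1_1620,  center: 1620.0, sigma: 22.0, a_pcw: 0.220, a_scw: 0.080, group: composition, direction: decrease}
  - {name: amide2_1545,        center: 1545.0, sigma: 9.0,  a_pcw: 0.100, a_scw: 0.020, group: composition, direction: decrease}
  - {name: ch2_scissor_1425,   center: 1425.0, sigma: 7.0,  a_pcw: 0.050, a_scw: 0.120, group: composition, direction: increase}
  - {name: oh_deform_1405,     center: 1405.0, sigma: 6.0,  a_pcw: 0.100, a_scw: 0.040, group: composition, direction: decrease}
  - {name: ch_bend_1365,       center: 1365.0, sigma: 6.0,  a_pcw: 0.050, a_scw: 0.140, group: maturation,  direction: increase}
  - {name: ch2_wag_1335,       center: 1335.0, sigma: 6.0,  a_pcw: 0.050, a_scw: 0.150, group: composition, direction: increase}
  - {name: ch2_wag_1315,       center: 1315.0, sigma: 6.0,  a_pcw: 0.060, a_scw: 0.200, group: maturation,  direction: increase}
  - {name: oh_nh_deform_1236,  center: 1236.0, sigma: 8.0,  a_pcw: 0.150, a_scw: 0.100, group: maturation,  direction: decrease}
  - {name: co_stretch_1200,    center: 1200.0, sigma: 8.0,  a_pcw: 0.090, a_scw: 0.160, group: composition, direction: increase}
  - {name: coc_stretch_1158,   center: 1158.0, sigma: 10.0, a_pcw: 0.170, a_scw: 0.300, group: composition, direction: increase}
  - {name: co_stretch_1104,    center: 1104.0, sigma: 10.0, a_pcw: 0.200, a_scw: 0.360, group: composition, direction: increase}
  - {name: co_stretch_1055,    center: 1055.0, sigma: 13.0, a_pcw: 0.500, a_scw: 0.850, group: composition, direction: increase}
  - {name: co_stretch_1028,    center: 1028.0, sigma: 11.0, a_pcw: 0.550, a_scw: 0.950, group: composition, direction: increase}
  - {name: co_stretch_985,     center: 985.0,  sigma: 10.0, a_pcw: 0.170, a_scw: 0.300, group: composition, direction: increase}
  - {name: glycosidic_895,     center: 895.0,  sigma: 6.0,  a_pcw: 0.030, a_scw: 0.130, group: maturation,  direction: increase}
  - {name: anchor_800,         center: 800.0,  sigma: 8.0,  a_pcw: 0.030, a_scw: 0.020, group: composition, direction: decrease}
  - {name: amorphous_730,      center: 730.0,  sigma: 9.0,  a_pcw: 0.110, a_scw: 0.160, group: maturation,  direction: increase}
  - {name: crystalline_708,    center: 708.0,  sigma: 9.0,  a_pcw: 0.050, a_scw: 0.200, group: maturation,  direction: increase}
  - {name: oh_oop_664,         center: 664.0,  sigma: 9.0,  a_pcw: 0.040, a_scw: 0.140, group: composition, direction: increase}
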