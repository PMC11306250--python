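# Shipped motor-variant parameter sets (nm, s, pN, mM units).
# rates: zero-load kinetics; mech: working stroke and stiffnesses;
# stopped_flow: solution-kinetics anchors used as simulation ground truths.
WT:
  rates: {k1_0: 4.7, k2_0: 46.0, d1: 1.8, d2: 2.8, k_att: 0.5}
  mech: {ws_total: 18.0, ws1: 15.0, ws2: 3.0, kappa_pre: 0.25, kappa_rigor: 0.25}
  stopped_flow: {k_adp: 3.7, k2: 20.8}
S267A:
  rates: {k1_0: 4.7, k2_0: 46.0, d1: 1.8, d2: 2.8, k_att: 0.5}
  mech: {ws_total: 17.4, ws1: 14.4, ws2: 3.0, kappa_pre: 0.25, kappa_rigor: 0.25}
  stopped_flow: {k_adp: 3.0, k2: 24.2}
S267E:
  rates: {k1_0: 19.4, k2_0: 55.0, d1: 1.8, d2: 2.8, k_att: 0.5}
  mech: {ws_total: 18.2, ws1: 15.2, ws2: 3.0, kappa_pre: 0.25, kappa_rigor: 0.35}
  stopped_flow: {k_adp: 16.3, k2: 46.4}
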