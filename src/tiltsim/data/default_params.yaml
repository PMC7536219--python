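sinus_node:
  T0:
    value: 1.1
    tag: fixed
    bounds:
    - 0.5
    - 2.0
    unit: s
  k_fs:
    value: 3.348917575556856
    tag: fitted
    bounds:
    - 0.0
    - 20.0
    unit: 1/a.u.
  c_sat_s:
    value: 3.0
    tag: fixed
    bounds:
    - 0.1
    - 50.0
    unit: a.u.
  k_fp:
    value: 0.21269287323174899
    tag: fitted
    bounds:
    - 0.0
    - 1.0
    unit: '-'
  v_sat_p:
    value: 1.5
    tag: fixed
    bounds:
    - 0.1
    - 20.0
    unit: a.u.
hemodynamics:
  C_wk:
    value: 1.914
    tag: fixed
    bounds:
    - 0.2
    - 10.0
    unit: a.u.
  tau_sys:
    value: 0.125
    tag: fixed
    bounds:
    - 0.05
    - 0.3
    unit: s
  R0:
    value: 0.7311602069184837
    tag: fitted
    bounds:
    - 0.1
    - 3.0
    unit: a.u.
  k_R:
    value: 0.046028342392774924
    tag: fitted
    bounds:
    - -1.0
    - 1.0
    unit: a.u./a.u.
  S_max:
    value: 120.0
    tag: fixed
    bounds:
    - 20.0
    - 500.0
    unit: mmHg
  s0:
    value: -23.058999354848204
    tag: fitted
    bounds:
    - -200.0
    - 200.0
    unit: mmHg
  k_sc:
    value: 10.0
    tag: fitted
    bounds:
    - 0.0
    - 200.0
    unit: mmHg/a.u.
  k_sT:
    value: 92.88119424810758
    tag: fitted
    bounds:
    - 0.0
    - 500.0
    unit: mmHg/s
baroreceptors:
  p0_u:
    value: 45.56701407678339
    tag: fitted
    bounds:
    - 0.0
    - 120.0
    unit: mmHg
  k_bp_u:
    value: 0.1
    tag: fitted
    bounds:
    - 0.0
    - 2.0
    unit: a.u./mmHg
  k_bd_u:
    value: 0.00125
    tag: fitted
    bounds:
    - 0.0
    - 0.1
    unit: a.u.s/mmHg
  p0_l:
    value: 45.86269917990205
    tag: fitted
    bounds:
    - 0.0
    - 120.0
    unit: mmHg
  k_bp_l:
    value: 0.1
    tag: fitted
    bounds:
    - 0.0
    - 2.0
    unit: a.u./mmHg
  k_bd_l:
    value: 0.00125
    tag: fitted
    bounds:
    - 0.0
    - 0.1
    unit: a.u.s/mmHg
tilt:
  p_hst_upper:
    value: 18.19042942938408
    tag: fitted
    bounds:
    - 0.0
    - 60.0
    unit: mmHg
  p_hst_lower:
    value: 20.873485183852484
    tag: fitted
    bounds:
    - 0.0
    - 80.0
    unit: mmHg
  alpha_test:
    value: 80.0
    tag: fixed
    bounds:
    - 10.0
    - 90.0
    unit: deg
sympathetic_heart:
  tau_s:
    value: 2.0
    tag: fixed
    bounds:
    - 0.2
    - 10.0
    unit: s
  theta_s:
    value: 3.3
    tag: fixed
    bounds:
    - 0.5
    - 8.0
    unit: s
  G_s:
    value: 6.0
    tag: fitted
    bounds:
    - 0.5
    - 30.0
    unit: a.u.
  k_ss:
    value: 1.5
    tag: fitted
    bounds:
    - 0.0
    - 10.0
    unit: 1/a.u.
  k_sb:
    value: 1.211091280641458
    tag: fitted
    bounds:
    - 0.0
    - 10.0
    unit: 1/a.u.
  k_sr:
    value: 0.2
    tag: fitted
    bounds:
    - 0.0
    - 5.0
    unit: '-'
  a_s:
    value: 8.440502206070851
    tag: fitted
    bounds:
    - -50.0
    - 80.0
    unit: '-'
sympathetic_vessel:
  tau_v:
    value: 2.0
    tag: fixed
    bounds:
    - 0.2
    - 10.0
    unit: s
  theta_v:
    value: 3.6
    tag: fixed
    bounds:
    - 0.5
    - 8.0
    unit: s
  G_v:
    value: 3.0
    tag: fitted
    bounds:
    - 0.5
    - 30.0
    unit: a.u.
  k_vv:
    value: 4.0
    tag: fitted
    bounds:
    - 0.0
    - 10.0
    unit: 1/a.u.
  k_vb:
    value: 4.840796378203857
    tag: fitted
    bounds:
    - 0.0
    - 10.0
    unit: 1/a.u.
  k_vr:
    value: 0.2
    tag: fitted
    bounds:
    - 0.0
    - 5.0
    unit: '-'
  a_v:
    value: 34.463895170100706
    tag: fitted
    bounds:
    - -50.0
    - 80.0
    unit: '-'
noradrenaline:
  tau_cc:
    value: 2.0
    tag: fitted
    bounds:
    - 0.2
    - 20.0
    unit: s
  k_cc:
    value: 0.03512548600565613
    tag: fitted
    bounds:
    - 0.0
    - 5.0
    unit: a.u./(a.u. s)
  theta_cc:
    value: 1.65
    tag: fixed
    bounds:
    - 0.0
    - 5.0
    unit: s
  tau_cv:
    value: 2.0
    tag: fitted
    bounds:
    - 0.2
    - 20.0
    unit: s
  k_cv:
    value: 0.612124086451042
    tag: fitted
    bounds:
    - 0.0
    - 5.0
    unit: a.u./(a.u. s)
  theta_cv:
    value: 1.65
    tag: fixed
    bounds:
    - 0.0
    - 5.0
    unit: s
parasympathetic:
  k_pb_u:
    value: 0.20166319598409896
    tag: fitted
    bounds:
    - 0.0
    - 5.0
    unit: '-'
  k_pb_l:
    value: 0.0
    tag: fixed
    bounds:
    - 0.0
    - 5.0
    unit: '-'
  k_pr:
    value: 0.5
    tag: fitted
    bounds:
    - 0.0
    - 5.0
    unit: a.u.
respiration:
  f_br:
    value: 0.25
    tag: from_data
    bounds:
    - 0.05
    - 0.6
    unit: Hz
  sigma2_xi:
    value: 0.0016
    tag: from_data
    bounds:
    - 0.0
    - 0.05
    unit: Hz^2
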