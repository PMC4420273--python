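# Calibrated cell parameters (frozen output of scripted calibration against
# measured properties: granule threshold ~25 mV above rest, mitral somatic
# tau_m ~50 ms, PG sag / rebound / low-threshold-spike phenotypes).
# Channel densities in S/m^2; geometry in um; resistivities in ohm.m^2 / ohm.m.

granule:
  leak_reversal: -50.0
  membrane_resistivity: 10.0
  axial_resistivity: 1.0
  soma:
    length: 12.0
    diameter: 12.0
    channels:
      Na_rat_ms: 10000.0
      K2_mit_usb_g: 1000.0
      KA_ms: 60.0
  dend:
    length: 250.0
    diameter: 3.0
    channels:
      Na_rat_ms: 200.0
      K2_mit_usb_g: 100.0
      KA_ms: 20.0
pg:
  leak_reversal: -65.0
  membrane_resistivity: 1.5
  axial_resistivity: 1.0
  ca_baseline: 5.0e-05
  ca_influx_scale: 0.02
  ca_decay_time: 20.0
  soma:
    length: 10.0
    diameter: 10.0
  dend:
    length: 100.0
    diameter: 2.0
  plateauing:
    membrane_resistivity: 3.0
    leak_reversal: -72.0
    soma_channels:
      Na_rat_ms: 1500.0
      K2_mit_usb_g: 200.0
      KA_bsg_yka_pg: 30.0
      TCa_d: 100.0
      Ih_cb: 4.0
      Kca_mit_usb_pg: 40.0
    dend_channels:
      TCa_d: 100.0
      Ih_cb: 4.0
  LTS:
    membrane_resistivity: 1.5
    leak_reversal: -62.0
    soma_channels:
      Na_rat_ms: 500.0
      K2_mit_usb_g: 300.0
      KA_bsg_yka_pg: 120.0
      TCa_d: 60.0
      Ih_cb: 2.5
      Kca_mit_usb_pg: 10.0
    dend_channels:
      TCa_d: 60.0
      Ih_cb: 2.5
mitral:
  leak_reversal: -65.0
  membrane_resistivity: 5.5
  axial_resistivity: 0.8
  ca_baseline: 5.0e-05
  ca_influx_scale: 0.01
  ca_decay_time: 10.0
  soma:
    length: 20.0
    diameter: 20.0
    channels:
      Na_mit_usb: 500.0
      K_mit_usb: 200.0
      K2_mit_usb: 100.0
      Kca_mit_usb: 50.0
      LCa3_mit_usb: 20.0
      KA_bsg_yka: 10.0
  initial_segment:
    channels:
      Na_mit_initialsegment_MS: 3000.0
      K2_mit_usb: 300.0
  primary:
    channels:
      Na_mit_usb: 300.0
      K2_mit_usb: 100.0
  tuft:
    channels:
      Na_mit_usb: 400.0
      K2_mit_usb: 120.0
  lateral:
    channels:
      Na_mit_usb: 150.0
      K2_mit_usb: 50.0
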