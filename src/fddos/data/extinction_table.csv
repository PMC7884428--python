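# Hemoglobin extinction coefficients and water absorption at the four
# analysis wavelengths. eps_* are ln-based specific absorption coefficients
# in 1/(cm*umol/L), converted from the standard literature compilation of
# molar (log10) extinction coefficients via eps = E[1/(cm*M)] * ln(10) / 1e6.
# mua_water is the absorption coefficient of pure water in 1/cm.
wavelength_nm,eps_hbo2,eps_hb,mua_water
690,6.3551e-4,4.7248e-3,0.0050
725,9.5672e-4,2.4762e-3,0.0160
785,1.7039e-3,2.2220e-3,0.0230
830,2.2427e-3,1.5957e-3,0.0300
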