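# Approximate (synthetic re-digitization) chromophore extinction compilation.
# eps_* in mm^-1 uM^-1 (natural log), mua_water in mm^-1 per unit water fraction.
wavelength_nm,eps_Hb,eps_HbO,eps_oxredCCO_diff,mua_water
670,6.437115e-04,6.678700e-05,5.987800e-04,4.200000e-04
680,5.545394e-04,6.393128e-05,5.527200e-04,4.700000e-04
690,4.725756e-04,6.356280e-05,5.112660e-04,5.500000e-04
700,4.132273e-04,6.678700e-05,4.836300e-04,6.200000e-04
710,3.547771e-04,7.231420e-05,4.606000e-04,8.000000e-04
720,3.053548e-04,7.867048e-05,4.490850e-04,1.250000e-03
730,2.538367e-04,8.981700e-05,4.490850e-04,2.100000e-03
740,2.569918e-04,1.027138e-04,4.606000e-04,2.700000e-03
750,3.236176e-04,1.173609e-04,4.836300e-04,2.700000e-03
755,3.456803e-04,1.257438e-04,4.997510e-04,2.680000e-03
760,3.566195e-04,1.349558e-04,5.181750e-04,2.650000e-03
765,3.385410e-04,1.420951e-04,5.458110e-04,2.580000e-03
770,3.021306e-04,1.496950e-04,5.757500e-04,2.500000e-03
780,2.476646e-04,1.635130e-04,6.563550e-04,2.400000e-03
790,2.079609e-04,1.741068e-04,7.599900e-04,2.450000e-03
800,1.754195e-04,1.879248e-04,8.751400e-04,2.200000e-03
810,1.651481e-04,1.989792e-04,9.902900e-04,2.500000e-03
820,1.597821e-04,2.109548e-04,1.093925e-03,2.800000e-03
830,1.595979e-04,2.243122e-04,1.151500e-03,3.200000e-03
840,1.594597e-04,2.353666e-04,1.139985e-03,3.900000e-03
850,1.592064e-04,2.436574e-04,1.082410e-03,4.300000e-03
860,1.603118e-04,2.501058e-04,9.902900e-04,4.900000e-03
870,1.639736e-04,2.588572e-04,8.866550e-04,5.600000e-03
880,1.666220e-04,2.657662e-04,7.830200e-04,6.100000e-03
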