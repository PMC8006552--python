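# Published per-cell hydraulic table for the two Larix sibirica rings of
# larix_t10_tracheidograms.csv (tree T10, rings 1994 and 2009, Shira,
# southern Siberia), transcribed once as the fixture of record for
# comparison tests. L_um and WT_um are the measured inputs; every other
# column is the published model output at the printed precision.
#
# Unit reading (the printed table headers are mutually inconsistent and are
# resolved as follows): the resistance columns Rwall/Rlum/R are in
# 10^-3 MPa s mm^-3 (= kPa s mm^-3) and K is in MPa^-1 s^-1 mm^3; this is
# the only reading under which K = 1/R holds row by row (e.g. R = 89e-3
# MPa s mm^-3 gives K = 11.2 MPa^-1 s^-1 mm^3).
# One transcription correction: ring T10-2009 pos 10 Rwall was printed as
# "11.999" where every neighbouring value uses a thin-space thousands
# separator; it is recorded here as 11999, consistent with the printed
# row total R = 13905 ≈ 11999 + 1905.
# Columns: CWA_um2 = cell-wall cross-sectional area; N_pit = pit count
# (printed as integer); Dm/Da/Dt = membrane/aperture/torus diameter (µm);
# cum_K = proportion of cumulative conductance, pith to bark.
ring,pos,wood_class,L_um,WT_um,CWA_um2,N_pit,Dm_um,Da_um,Dt_um,Rwall_kPa_s_mm3,Rlum_kPa_s_mm3,R_kPa_s_mm3,K_MPa_s_mm3,cum_K
T10-1994,1,earlywood,36.09,3.58,472.91,52,25.00,6.25,12.50,16,73,89,11.20,0.17
T10-1994,2,earlywood,29.68,3.86,461.07,42,20.77,5.19,10.39,39,107,146,6.84,0.27
T10-1994,3,earlywood,25.79,3.81,425.10,37,18.06,4.51,9.03,74,136,210,4.76,0.35
T10-1994,4,earlywood,20.76,3.85,391.29,30,14.53,3.63,7.27,204,210,415,2.41,0.38
T10-1994,5,earlywood,23.46,3.91,417.59,34,16.42,4.10,8.21,117,166,283,3.54,0.44
T10-1994,6,earlywood,28.21,3.95,460.14,40,19.75,4.94,9.87,50,119,169,5.92,0.53
T10-1994,7,earlywood,38.41,4.12,563.87,55,25.00,6.25,12.50,16,75,92,10.93,0.69
T10-1994,8,earlywood,40.12,4.35,610.06,57,25.00,6.25,12.50,16,75,91,11.02,0.86
T10-1994,9,earlywood,34.57,5.12,661.61,49,24.20,6.05,12.10,23,112,135,7.41,0.97
T10-1994,10,earlywood,20.94,6.07,618.69,30,14.66,3.66,7.33,263,325,589,1.70,1.00
T10-1994,11,latewood,11.47,7.14,592.18,16,8.03,2.01,4.01,5416,1451,6867,0.15,1.00
T10-1994,12,latewood,9.49,7.47,589.82,14,6.64,1.66,3.32,14194,2442,16636,0.06,1.00
T10-1994,13,latewood,7.27,7.56,563.84,10,5.09,1.27,2.54,53267,4937,58204,0.02,1.00
T10-1994,14,latewood,6.72,6.97,511.59,10,4.71,1.18,2.35,73167,5564,78731,0.01,1.00
T10-1994,15,latewood,6.18,5.75,415.97,9,4.32,1.08,2.16,94628,6103,100731,0.01,1.00
T10-1994,16,latewood,3.60,5.27,354.20,5,2.52,0.63,1.26,1297171,33072,1330243,0.00,1.00
T10-1994,17,latewood,3.17,4.69,311.06,5,2.22,0.55,1.11,2221219,49284,2270504,0.00,1.00
T10-1994,18,latewood,3.26,4.39,292.08,5,2.28,0.57,1.14,1821187,43883,1865069,0.00,1.00
T10-1994,19,latewood,3.28,4.47,297.50,5,2.30,0.57,1.15,1786667,43052,1829719,0.00,1.00
T10-1994,20,latewood,5.33,4.37,309.02,8,3.73,0.93,1.87,157023,8500,165523,0.01,1.00
T10-1994,21,latewood,3.29,3.75,249.41,5,2.30,0.58,1.15,1546563,41385,1587949,0.00,1.00
T10-2009,1,earlywood,43.71,3.65,537.91,63,25.00,6.25,12.50,13,56,70,14.36,0.11
T10-2009,2,earlywood,52.40,3.57,588.10,75,25.00,6.25,12.50,11,44,55,18.27,0.25
T10-2009,3,earlywood,50.27,3.51,562.95,72,25.00,6.25,12.50,11,45,57,17.63,0.39
T10-2009,4,earlywood,48.22,3.63,568.39,69,25.00,6.25,12.50,12,49,61,16.31,0.51
T10-2009,5,earlywood,49.29,3.76,595.77,70,25.00,6.25,12.50,12,49,61,16.30,0.64
T10-2009,6,earlywood,49.66,3.78,601.81,71,25.00,6.25,12.50,12,49,61,16.37,0.76
T10-2009,7,earlywood,50.07,3.95,632.68,72,25.00,6.25,12.50,12,51,63,15.90,0.88
T10-2009,8,earlywood,44.53,4.45,663.30,64,25.00,6.25,12.50,14,67,81,12.31,0.98
T10-2009,9,earlywood,24.09,5.56,601.55,34,16.86,4.22,8.43,128,224,351,2.85,1.00
T10-2009,10,latewood,9.49,6.08,480.34,14,6.64,1.66,3.32,11999,1905,13905,0.07,1.00
T10-2009,11,latewood,5.59,5.79,412.11,8,3.91,0.98,1.96,156003,8299,164303,0.01,1.00
T10-2009,12,latewood,3.98,4.69,318.83,6,2.78,0.70,1.39,711823,22694,734517,0.00,1.00
T10-2009,13,latewood,3.16,4.28,284.05,5,2.21,0.55,1.10,2113775,49044,2162819,0.00,1.00
T10-2009,14,latewood,3.90,4.43,300.44,6,2.73,0.68,1.37,746575,23792,770367,0.00,1.00
T10-2009,15,latewood,3.53,4.22,283.31,5,2.47,0.62,1.24,1191075,33179,1224254,0.00,1.00
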