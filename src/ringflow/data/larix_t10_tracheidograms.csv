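# Representative radial files (tracheidograms) of two annual rings of a
# mature Larix sibirica tree (tree T10, rings 1994 and 2009) growing near
# Shira, southern Siberia. Transcribed once from the published per-cell
# measurement table of those two rings; this file is the versioned fixture
# of record for the worked example and for tests.
# Columns: ring identifier, 1-based position from pith to bark,
# L_um = radial lumen diameter (µm), WT_um = radial wall thickness (µm).
# Use the `larix_25` parameter profile (membrane cap 25 µm) with these data.
ring,pos,L_um,WT_um
T10-1994,1,36.09,3.58
T10-1994,2,29.68,3.86
T10-1994,3,25.79,3.81
T10-1994,4,20.76,3.85
T10-1994,5,23.46,3.91
T10-1994,6,28.21,3.95
T10-1994,7,38.41,4.12
T10-1994,8,40.12,4.35
T10-1994,9,34.57,5.12
T10-1994,10,20.94,6.07
T10-1994,11,11.47,7.14
T10-1994,12,9.49,7.47
T10-1994,13,7.27,7.56
T10-1994,14,6.72,6.97
T10-1994,15,6.18,5.75
T10-1994,16,3.60,5.27
T10-1994,17,3.17,4.69
T10-1994,18,3.26,4.39
T10-1994,19,3.28,4.47
T10-1994,20,5.33,4.37
T10-1994,21,3.29,3.75
T10-2009,1,43.71,3.65
T10-2009,2,52.40,3.57
T10-2009,3,50.27,3.51
T10-2009,4,48.22,3.63
T10-2009,5,49.29,3.76
T10-2009,6,49.66,3.78
T10-2009,7,50.07,3.95
T10-2009,8,44.53,4.45
T10-2009,9,24.09,5.56
T10-2009,10,9.49,6.08
T10-2009,11,5.59,5.79
T10-2009,12,3.98,4.69
T10-2009,13,3.16,4.28
T10-2009,14,3.90,4.43
T10-2009,15,3.53,4.22
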