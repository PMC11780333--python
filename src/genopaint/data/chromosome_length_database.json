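{
 "rice": {
  "chr01": 43270923,
  "chr02": 35937250,
  "chr03": 36413819,
  "chr04": 35502694,
  "chr05": 29958434,
  "chr06": 31248787,
  "chr07": 29697621,
  "chr08": 28443022,
  "chr09": 23012720,
  "chr10": 23207287,
  "chr11": 29021106,
  "chr12": 27531856
 },
 "sorghum": {
  "Chr01": 80884392,
  "Chr02": 77742459,
  "Chr03": 74386277,
  "Chr04": 68658214,
  "Chr05": 71854669,
  "Chr06": 61277060,
  "Chr07": 65505356,
  "Chr08": 62686529,
  "Chr09": 59416394,
  "Chr10": 61233695
 },
 "maize": {
  "chr1": 307041717,
  "chr2": 244442276,
  "chr3": 235667834,
  "chr4": 246994605,
  "chr5": 223902240,
  "chr6": 174033170,
  "chr7": 182381542,
  "chr8": 181122637,
  "chr9": 159769782,
  "chr10": 150982314
 },
 "wheat": {
  "chr1A": 594102056,
  "chr1B": 689851870,
  "chr1D": 495453186,
  "chr2A": 780798557,
  "chr2B": 801256715,
  "chr2D": 651852609,
  "chr3A": 750843639,
  "chr3B": 830829764,
  "chr3D": 615552423,
  "chr4A": 744588157,
  "chr4B": 673617499,
  "chr4D": 509857067,
  "chr5A": 709773743,
  "chr5B": 713149757,
  "chr5D": 566080677,
  "chr6A": 618079260,
  "chr6B": 720988478,
  "chr6D": 473592718,
  "chr7A": 736706236,
  "chr7B": 750620385,
  "chr7D": 638686055
 },
 "barley": {
  "chr1H": 558535432,
  "chr2H": 768075024,
  "chr3H": 699711114,
  "chr4H": 647060158,
  "chr5H": 670030160,
  "chr6H": 583380513,
  "chr7H": 657224000
 },
 "soybean": {
  "Gm01": 56831624,
  "Gm02": 48577505,
  "Gm03": 45779781,
  "Gm04": 52389146,
  "Gm05": 42234498,
  "Gm06": 51416486,
  "Gm07": 44630646,
  "Gm08": 47837940,
  "Gm09": 50189764,
  "Gm10": 51566898,
  "Gm11": 34766867,
  "Gm12": 40091314,
  "Gm13": 45874162,
  "Gm14": 49042192,
  "Gm15": 51756343,
  "Gm16": 37887014,
  "Gm17": 41641366,
  "Gm18": 58018742,
  "Gm19": 50746916,
  "Gm20": 47904181
 },
 "tomato": {
  "chr1": 90863682,
  "chr2": 53473368,
  "chr3": 65298490,
  "chr4": 64459972,
  "chr5": 65269487,
  "chr6": 47258699,
  "chr7": 67883646,
  "chr8": 63995357,
  "chr9": 68513564,
  "chr10": 64792705,
  "chr11": 54379777,
  "chr12": 66688036
 },
 "arabidopsis": {
  "Chr1": 30427671,
  "Chr2": 19698289,
  "Chr3": 23459830,
  "Chr4": 18585056,
  "Chr5": 26975502
 }
}
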