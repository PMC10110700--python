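eye,longitude_deg,upper_deg,lower_deg
right,-180.000000,-1.000000,1.000000
right,-174.000000,-1.000000,1.000000
right,-168.000000,-1.000000,1.000000
right,-162.000000,-1.000000,1.000000
right,-156.000000,-1.000000,1.000000
right,-150.000000,-1.000000,1.000000
right,-144.000000,-1.000000,1.000000
right,-138.000000,-1.000000,1.000000
right,-132.000000,-1.000000,1.000000
right,-126.000000,-1.000000,1.000000
right,-120.000000,-1.000000,1.000000
right,-114.000000,-1.000000,1.000000
right,-108.000000,-1.000000,1.000000
right,-102.000000,-1.000000,1.000000
right,-96.000000,-1.000000,1.000000
right,-90.000000,-1.000000,1.000000
right,-84.000000,-1.000000,1.000000
right,-78.000000,-1.000000,1.000000
right,-72.000000,-1.000000,1.000000
right,-66.000000,-1.000000,1.000000
right,-60.000000,-1.000000,1.000000
right,-54.000000,-1.000000,1.000000
right,-48.000000,-1.000000,1.000000
right,-42.000000,-1.000000,1.000000
right,-36.000000,-1.000000,1.000000
right,-30.000000,-1.000000,1.000000
right,-24.000000,-1.000000,1.000000
right,-18.000000,0.000000,0.000000
right,-12.000000,37.546771,-43.804566
right,-6.000000,41.638444,-48.578184
right,0.000000,45.075936,-52.588592
right,6.000000,48.000000,-56.000000
right,12.000000,50.499901,-58.916551
right,18.000000,52.636109,-61.408794
right,24.000000,54.451446,-63.526687
right,30.000000,55.977138,-65.306661
right,36.000000,57.236352,-66.775744
right,42.000000,58.246373,-67.954102
right,48.000000,59.019997,-68.856663
right,54.000000,59.566434,-69.494172
right,60.000000,59.891903,-69.873886
right,66.000000,60.000000,-70.000000
right,72.000000,59.891903,-69.873886
right,78.000000,59.566434,-69.494172
right,84.000000,59.019997,-68.856663
right,90.000000,58.246373,-67.954102
right,96.000000,57.236352,-66.775744
right,102.000000,55.977138,-65.306661
right,108.000000,54.451446,-63.526687
right,114.000000,52.636109,-61.408794
right,120.000000,50.499901,-58.916551
right,126.000000,48.000000,-56.000000
right,132.000000,45.075936,-52.588592
right,138.000000,41.638444,-48.578184
right,144.000000,37.546771,-43.804566
right,150.000000,0.000000,0.000000
right,156.000000,-1.000000,1.000000
right,162.000000,-1.000000,1.000000
right,168.000000,-1.000000,1.000000
right,174.000000,-1.000000,1.000000
left,-180.000000,-1.000000,1.000000
left,-174.000000,-1.000000,1.000000
left,-168.000000,-1.000000,1.000000
left,-162.000000,-1.000000,1.000000
left,-156.000000,-1.000000,1.000000
left,-150.000000,0.000000,0.000000
left,-144.000000,37.546771,-43.804566
left,-138.000000,41.638444,-48.578184
left,-132.000000,45.075936,-52.588592
left,-126.000000,48.000000,-56.000000
left,-120.000000,50.499901,-58.916551
left,-114.000000,52.636109,-61.408794
left,-108.000000,54.451446,-63.526687
left,-102.000000,55.977138,-65.306661
left,-96.000000,57.236352,-66.775744
left,-90.000000,58.246373,-67.954102
left,-84.000000,59.019997,-68.856663
left,-78.000000,59.566434,-69.494172
left,-72.000000,59.891903,-69.873886
left,-66.000000,60.000000,-70.000000
left,-60.000000,59.891903,-69.873886
left,-54.000000,59.566434,-69.494172
left,-48.000000,59.019997,-68.856663
left,-42.000000,58.246373,-67.954102
left,-36.000000,57.236352,-66.775744
left,-30.000000,55.977138,-65.306661
left,-24.000000,54.451446,-63.526687
left,-18.000000,52.636109,-61.408794
left,-12.000000,50.499901,-58.916551
left,-6.000000,48.000000,-56.000000
left,0.000000,45.075936,-52.588592
left,6.000000,41.638444,-48.578184
left,12.000000,37.546771,-43.804566
left,18.000000,0.000000,0.000000
left,24.000000,-1.000000,1.000000
left,30.000000,-1.000000,1.000000
left,36.000000,-1.000000,1.000000
left,42.000000,-1.000000,1.000000
left,48.000000,-1.000000,1.000000
left,54.000000,-1.000000,1.000000
left,60.000000,-1.000000,1.000000
left,66.000000,-1.000000,1.000000
left,72.000000,-1.000000,1.000000
left,78.000000,-1.000000,1.000000
left,84.000000,-1.000000,1.000000
left,90.000000,-1.000000,1.000000
left,96.000000,-1.000000,1.000000
left,102.000000,-1.000000,1.000000
left,108.000000,-1.000000,1.000000
left,114.000000,-1.000000,1.000000
left,120.000000,-1.000000,1.000000
left,126.000000,-1.000000,1.000000
left,132.000000,-1.000000,1.000000
left,138.000000,-1.000000,1.000000
left,144.000000,-1.000000,1.000000
left,150.000000,-1.000000,1.000000
left,156.000000,-1.000000,1.000000
left,162.000000,-1.000000,1.000000
left,168.000000,-1.000000,1.000000
left,174.000000,-1.000000,1.000000
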