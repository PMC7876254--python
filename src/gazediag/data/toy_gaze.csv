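participant_id,clip_id,t_ms,x_px,y_px,valid
toy1,still,0,754.2,670.7,1
toy1,still,20,655.5,359.4,1
toy1,still,40,675.6,217.8,1
toy1,still,60,451.3,442.5,1
toy1,still,80,480.8,561.0,1
toy1,still,100,857.9,654.1,1
toy1,still,120,351.0,335.2,1
toy1,still,140,883.0,330.1,1
toy1,still,160,780.3,599.1,1
toy1,still,180,685.5,534.0,1
toy1,still,200,441.1,211.0,1
toy1,still,220,377.8,261.5,1
toy1,drawing,0,572.5,438.7,1
toy1,drawing,20,700.2,600.4,1
toy1,drawing,40,552.4,257.2,1
toy1,drawing,60,453.7,445.0,1
toy1,drawing,80,351.2,558.4,1
toy1,drawing,100,498.6,505.1,1
toy1,drawing,120,658.9,612.7,1
toy1,drawing,140,831.8,625.1,1
toy1,drawing,160,616.8,430.3,1
toy1,drawing,180,314.8,667.5,1
toy2,still,0,501.8,266.3,1
toy2,still,20,418.0,380.6,1
toy2,still,40,440.0,276.2,1
toy2,still,60,556.0,596.2,1
toy2,still,80,738.0,211.9,1
toy2,still,100,452.2,659.0,1
toy2,still,120,860.5,355.5,1
toy2,still,140,760.8,222.8,1
toy2,still,160,844.5,285.8,1
toy2,still,180,502.5,389.3,1
toy2,still,200,623.3,452.5,1
toy2,still,220,377.1,251.2,1
toy2,drawing,0,384.5,241.0,1
toy2,drawing,20,432.9,558.6,1
toy2,drawing,40,741.6,570.2,1
toy2,drawing,60,383.0,655.0,1
toy2,drawing,80,510.7,277.4,1
toy2,drawing,100,354.2,265.3,1
toy2,drawing,120,791.2,512.9,1
toy2,drawing,140,554.1,431.6,1
toy2,drawing,160,581.3,462.2,1
toy2,drawing,180,327.1,533.5,1
toy3,still,0,611.5,237.8,1
toy3,still,20,319.7,568.3,1
toy3,still,40,626.8,263.0,1
toy3,still,60,521.5,519.6,1
toy3,still,80,,,0
toy3,still,100,485.1,451.6,1
toy3,still,120,421.9,517.6,1
toy3,still,140,712.4,311.2,1
toy3,still,160,339.8,286.1,1
toy3,still,180,,,0
toy3,still,200,317.9,467.1,1
toy3,still,220,885.2,383.1,1
toy3,drawing,0,586.7,534.3,1
toy3,drawing,20,881.0,305.2,1
toy3,drawing,40,488.0,537.1,1
toy3,drawing,60,494.9,419.4,1
toy3,drawing,80,,,0
toy3,drawing,100,363.4,698.7,1
toy3,drawing,120,685.0,629.9,1
toy3,drawing,140,561.2,335.6,1
toy3,drawing,160,472.8,562.9,1
toy3,drawing,180,,,0
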